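"""Paired predictive evaluations, conditional probabilities and rank profiles."""

import numpy as np
import pandas as pd
import pytest

from missense_states import (
    conditional_positive_probability,
    paired_classification_eval,
    paired_regression_eval,
    prepare_classification_set,
    rank_by_state,
)


def _variants(n, seed=0, prefix="chr1"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "chrom": [prefix] * n,
            "pos": np.arange(1, n + 1),
            "ref": ["A"] * n,
            "alt": ["T"] * n,
            "score": rng.random(n),
        }
    )


def test_prepare_classification_set_balances_and_excludes_overlap():
    positives = _variants(100, seed=1)
    negatives = _variants(5000, seed=2)
    # make the first 50 negatives collide with positives
    negatives.iloc[:50, negatives.columns.get_loc("pos")] = positives["pos"].iloc[:50]
    out = prepare_classification_set(positives, negatives, seed=3)
    assert (out["label"] == 1).sum() == 100
    assert (out["label"] == 0).sum() == 100
    neg_keys = set(
        map(tuple, out.loc[out["label"] == 0, ["chrom", "pos", "ref", "alt"]].itertuples(index=False))
    )
    pos_keys = set(
        map(tuple, positives[["chrom", "pos", "ref", "alt"]].itertuples(index=False))
    )
    assert not neg_keys & pos_keys
    # deterministic under the seed
    again = prepare_classification_set(positives, negatives, seed=3)
    pd.testing.assert_frame_equal(out, again)


def test_prepare_classification_set_insufficient_negatives():
    with pytest.raises(ValueError):
        prepare_classification_set(_variants(100), _variants(50, seed=9), seed=0)


def test_paired_classification_eval_perfect_score_ceiling():
    """If the score equals the label, both models reach AUROC 1 and the
    improvement is 0."""
    rng = np.random.default_rng(4)
    n = 400
    labels = rng.integers(0, 2, n)
    df = pd.DataFrame(
        {
            "label": labels,
            "perfect": labels.astype(float),
            "state": rng.integers(1, 4, n),
        }
    )
    res = paired_classification_eval(df, "perfect", seed=0)
    assert res["auroc_score_only"] == pytest.approx(1.0)
    assert res["auroc_with_states"] == pytest.approx(1.0)
    assert res["percent_improvement"] == pytest.approx(0.0)


def test_paired_classification_eval_drops_missing_and_reports():
    rng = np.random.default_rng(5)
    n = 300
    score = rng.random(n)
    score[:30] = np.nan
    labels = (score > 0.5).astype(float)
    labels[np.isnan(score)] = rng.integers(0, 2, 30)
    df = pd.DataFrame(
        {"label": labels.astype(int), "s": score, "state": rng.integers(1, 3, n)}
    )
    res = paired_classification_eval(df, "s", seed=1)
    assert res["n_dropped"] == 30
    assert res["n_used"] == 270


def test_paired_classification_eval_detects_state_effects():
    """Labels with strong per-state offsets beyond the score: improvement > 5%."""
    rng = np.random.default_rng(6)
    n = 3000
    score = rng.random(n)
    state = rng.integers(1, 5, n)
    offsets = np.array([-2.0, -0.7, 0.7, 2.0])[state - 1]
    p = 1.0 / (1.0 + np.exp(-(2.0 * score - 1.0 + offsets)))
    df = pd.DataFrame(
        {"label": (rng.random(n) < p).astype(int), "s": score, "state": state}
    )
    res = paired_classification_eval(df, "s", seed=2)
    assert res["percent_improvement"] > 5.0


def test_paired_regression_eval_affine_score_is_perfect():
    rng = np.random.default_rng(7)
    n = 200
    score = rng.random(n)
    df = pd.DataFrame(
        {
            "measurement": "m1",
            "value": 2.0 * score + 1.0,
            "s": score,
            "state": rng.integers(1, 4, n),
        }
    )
    res = paired_regression_eval(df, "s", seed=0)
    assert res["spearman_score_only"].iloc[0] == pytest.approx(1.0)
    assert res["spearman_with_states"].iloc[0] == pytest.approx(1.0)


def test_paired_regression_eval_state_offsets_help():
    rng = np.random.default_rng(8)
    n = 2000
    score = rng.random(n)
    state = rng.integers(1, 5, n)
    offsets = np.array([-1.0, -0.3, 0.3, 1.0])[state - 1]
    value = score + offsets + rng.normal(0, 0.3, n)
    df = pd.DataFrame({"measurement": "m1", "value": value, "s": score, "state": state})
    res = paired_regression_eval(df, "s", seed=1)
    assert (
        res["spearman_with_states"].iloc[0] > res["spearman_score_only"].iloc[0]
    )


def test_paired_regression_eval_shuffled_truth_is_null():
    """Against a shuffled measurement both models are uninformative: the
    mean |Spearman| over seeds is near zero."""
    n = 2000
    r_only, r_with = [], []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        score = rng.random(n)
        df = pd.DataFrame(
            {
                "measurement": "m1",
                "value": rng.permutation(score),
                "s": score,
                "state": rng.integers(1, 4, n),
            }
        )
        res = paired_regression_eval(df, "s", seed=seed)
        r_only.append(abs(res["spearman_score_only"].iloc[0]))
        r_with.append(abs(res["spearman_with_states"].iloc[0]))
    assert np.mean(r_only) < 0.05
    assert np.mean(r_with) < 0.05


def test_paired_regression_eval_skips_constant_measurement():
    rng = np.random.default_rng(10)
    df = pd.DataFrame(
        {
            "measurement": ["flat"] * 50 + ["ok"] * 50,
            "value": [1.0] * 50 + list(rng.random(50)),
            "s": rng.random(100),
            "state": rng.integers(1, 3, 100),
        }
    )
    res = paired_regression_eval(df, "s", seed=0)
    assert list(res["measurement"]) == ["ok"]


def test_conditional_positive_probability_designed_rates():
    """Per-state positive rates {0.9, 0.5, 0.1} above threshold are recovered."""
    rng = np.random.default_rng(11)
    rates = {1: 0.9, 2: 0.5, 3: 0.1}
    frames = []
    for s, r in rates.items():
        n = 1000
        frames.append(
            pd.DataFrame(
                {
                    "state": s,
                    "s": rng.uniform(0.8, 1.0, n),  # all above threshold
                    "label": (rng.random(n) < r).astype(int),
                }
            )
        )
    # a state with nothing above threshold
    frames.append(pd.DataFrame({"state": 4, "s": [0.1, 0.2], "label": [1, 0]}))
    df = pd.concat(frames, ignore_index=True)
    res = conditional_positive_probability(df, "s", threshold=0.75)
    for s, r in rates.items():
        assert res["per_state"][s] == pytest.approx(r, abs=0.03)
    assert np.isnan(res["per_state"][4])
    # weighted combination over states recovers the overall positive rate
    qual = df[df["s"] > 0.75]
    weights = qual.groupby("state").size()
    combined = (res["per_state"].dropna() * weights).sum() / weights.sum()
    assert combined == pytest.approx(qual["label"].mean())


def test_rank_by_state_predictor_equal_and_reversed_dms():
    rng = np.random.default_rng(12)
    n = 300
    value = rng.random(n)
    df = pd.DataFrame(
        {
            "protein": "p1",
            "state": rng.integers(1, 5, n),
            "value": value,
            "same": value,  # identical to the measurement
            "reversed": -value,  # perfectly anti-correlated
        }
    )
    res = rank_by_state(df, ["same", "reversed"], dms_col="value")
    assert res.predictor_vs_dms["same"] == pytest.approx(1.0)
    assert res.predictor_vs_dms["reversed"] == pytest.approx(-1.0)
    # scaled ranks live in [0, 1] and DMS ranks span the full range per protein
    prof = res.state_profiles
    assert ((prof >= 0) & (prof <= 1)).all().all()


def test_rank_by_state_hand_set_averages():
    """Three states, two predictors, hand-set values: per-state average
    scaled ranks match direct computation."""
    df = pd.DataFrame(
        {
            "protein": ["p"] * 6,
            "state": [1, 1, 2, 2, 3, 3],
            "value": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            "a": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            "b": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        }
    )
    res = rank_by_state(df, ["a", "b"], dms_col="value")
    # damage rank of value v among 6 distinct values (lower = more damaging):
    # scaled = (rank of -v - 1)/5, so values 6..1 -> 0, .2, .4, .6, .8, 1
    prof = res.state_profiles
    assert prof.loc[1, "a"] == pytest.approx(0.1)
    assert prof.loc[2, "a"] == pytest.approx(0.5)
    assert prof.loc[3, "a"] == pytest.approx(0.9)
    assert prof.loc[1, "b"] == pytest.approx(0.9)
    assert prof.loc[1, "DMS"] == pytest.approx(0.1)
    # leaderboard: 'a' tracks DMS perfectly, 'b' anti-tracks
    assert res.leaderboard["a"] == pytest.approx(1.0)
    assert res.leaderboard["b"] == pytest.approx(-1.0)


def test_rank_by_state_excludes_tiny_proteins():
    df = pd.DataFrame(
        {
            "protein": ["p1"] * 4 + ["lonely"],
            "state": [1, 1, 2, 2, 1],
            "value": [1.0, 2.0, 3.0, 4.0, 5.0],
            "a": [1.0, 2.0, 3.0, 4.0, 5.0],
        }
    )
    res = rank_by_state(df, ["a"], dms_col="value")
    # the single-variant protein contributes nothing
    assert res.state_profiles["DMS"].notna().all()
    assert len(res.state_profiles) == 2
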