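"""Predictive information added by state annotations over individual scores.

Paired evaluations train two models per score — one on the score alone, one
on the score plus one-hot state indicators — under the same cross-validation
split, and report the relative improvement of the augmented model.  For
classification (pathogenic vs benign-like labels) the models are logistic
regressions scored by pooled out-of-fold AUROC; for continuous functional
measurements (DMS-style) they are linear regressions scored by Spearman
correlation of pooled out-of-fold predictions with the truth.

One-hot state features use K-1 indicators plus an intercept (dropping one
level avoids collinearity without changing the fitted probabilities).  The
logistic models carry a weak, identical ridge penalty (C = 1e3) so the
score-only vs score-plus-states comparison is fair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "prepare_classification_set",
    "paired_classification_eval",
    "paired_regression_eval",
    "conditional_positive_probability",
    "rank_by_state",
    "RankByStateResult",
]

_KEY = ["chrom", "pos", "ref", "alt"]

#: weak ridge strength for the paired logistic models (documented constant)
LOGISTIC_C = 1e3


def prepare_classification_set(
    positives: pd.DataFrame, negatives: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Balanced labeled set: all positives plus an equal-size negative subsample.

    Negatives sharing a (chrom, pos, ref, alt) key with a positive are
    excluded first; the remainder is down-sampled without replacement to the
    positive count using the seeded RNG.  Output carries ``label`` (1 =
    positive).
    """
    pos_keys = set(map(tuple, positives[_KEY].itertuples(index=False)))
    neg_mask = [
        tuple(row) not in pos_keys
        for row in negatives[_KEY].itertuples(index=False)
    ]
    neg = negatives[np.asarray(neg_mask)]
    n_pos = len(positives)
    if len(neg) < n_pos:
        raise ValueError(
            f"only {len(neg)} eligible negatives for {n_pos} positives"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(len(neg), size=n_pos, replace=False)
    neg = neg.iloc[np.sort(take)]
    pos = positives.copy()
    pos["label"] = 1
    neg = neg.copy()
    neg["label"] = 0
    return pd.concat([pos, neg], ignore_index=True)


def _one_hot_states(states: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """K-1 indicator columns (first level dropped)."""
    return np.column_stack([(states == s).astype(float) for s in levels[1:]])


def paired_classification_eval(
    labeled: pd.DataFrame,
    score_name: str,
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Score-only vs score-plus-states logistic AUROC under shared CV folds.

    Rows with a missing value of ``score_name`` are dropped (and counted).
    Stratified folds; out-of-fold predicted probabilities are pooled into one
    overall AUROC per feature set.  Returns a dict with both AUROCs, the
    percent improvement 100*(with - without)/without, and row accounting.
    """
    score = pd.to_numeric(labeled[score_name], errors="coerce").to_numpy(float)
    keep = ~np.isnan(score)
    n_dropped = int((~keep).sum())
    df = labeled[keep]
    score = score[keep]
    y = df["label"].to_numpy(int)
    states = df["state"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    levels = np.unique(states)

    x1 = score[:, None]
    x2 = np.column_stack([score[:, None], _one_hot_states(states, levels)])

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred1 = np.empty(len(y))
    pred2 = np.empty(len(y))
    for train, test in cv.split(x1, y):
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training fold contains a single class")
        m1 = LogisticRegression(C=LOGISTIC_C, max_iter=1000)
        m2 = LogisticRegression(C=LOGISTIC_C, max_iter=1000)
        m1.fit(x1[train], y[train])
        m2.fit(x2[train], y[train])
        pred1[test] = m1.predict_proba(x1[test])[:, 1]
        pred2[test] = m2.predict_proba(x2[test])[:, 1]

    auc1 = float(roc_auc_score(y, pred1))
    auc2 = float(roc_auc_score(y, pred2))
    return {
        "score": score_name,
        "n_used": int(len(y)),
        "n_dropped": n_dropped,
        "auroc_score_only": auc1,
        "auroc_with_states": auc2,
        "percent_improvement": 100.0 * (auc2 - auc1) / auc1,
    }


def paired_regression_eval(
    measurements: pd.DataFrame,
    score_name: str,
    n_folds: int = 5,
    seed: int = 0,
    measurement_col: str = "measurement",
    value_col: str = "value",
) -> pd.DataFrame:
    """Per-measurement paired linear-regression evaluation on DMS-style data.

    For every measurement id: K-fold CV, two linear models (score vs score +
    one-hot states) fit on the training folds, pooled held-out predictions
    scored by Spearman correlation with the measured values.  Measurements
    with constant values (Spearman undefined) or fewer than ``2 * n_folds``
    rows are skipped with a log entry.  Returns one row per evaluated
    measurement plus the percent improvement.
    """
    rows = []
    for mid, sub in measurements.groupby(measurement_col):
        score = pd.to_numeric(sub[score_name], errors="coerce").to_numpy(float)
        keep = ~np.isnan(score)
        sub = sub[keep]
        score = score[keep]
        y = pd.to_numeric(sub[value_col], errors="coerce").to_numpy(float)
        if len(y) < 2 * n_folds:
            logger.info("measurement %s too small (%d rows); skipped", mid, len(y))
            continue
        if np.std(y) == 0:
            logger.info("measurement %s is constant; skipped", mid)
            continue
        states = sub["state"].to_numpy()
        levels = np.unique(states)
        x1 = score[:, None]
        x2 = np.column_stack([x1, _one_hot_states(states, levels)])
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        pred1 = np.empty(len(y))
        pred2 = np.empty(len(y))
        for train, test in cv.split(x1):
            m1 = LinearRegression().fit(x1[train], y[train])
            m2 = LinearRegression().fit(x2[train], y[train])
            pred1[test] = m1.predict(x1[test])
            pred2[test] = m2.predict(x2[test])
        r1 = float(spearmanr(pred1, y).statistic)
        r2 = float(spearmanr(pred2, y).statistic)
        rows.append(
            {
                "measurement": mid,
                "score": score_name,
                "n": int(len(y)),
                "spearman_score_only": r1,
                "spearman_with_states": r2,
                "percent_improvement": 100.0 * (r2 - r1) / abs(r1)
                if r1 != 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def conditional_positive_probability(
    labeled: pd.DataFrame, score_name: str, threshold: float
) -> dict:
    """Per-state P(positive | score > threshold), with cross-state mean and SD.

    States with no variant above the threshold are reported as NaN and
    excluded from the mean/SD.
    """
    score = pd.to_numeric(labeled[score_name], errors="coerce").to_numpy(float)
    qualifying = score > threshold
    states = labeled["state"].to_numpy()
    y = labeled["label"].to_numpy(int)
    probs = {}
    for s in np.unique(states):
        sel = qualifying & (states == s)
        probs[int(s)] = float(y[sel].mean()) if sel.any() else np.nan
    series = pd.Series(probs, name="p_positive")
    series.index.name = "state"
    valid = series.dropna()
    return {
        "per_state": series,
        "mean": float(valid.mean()) if len(valid) else np.nan,
        "sd": float(valid.std(ddof=0)) if len(valid) else np.nan,
    }


def _scaled_damage_rank(values: np.ndarray, higher_is_damaging: bool) -> np.ndarray:
    """Ranks scaled to [0, 1] with 1 = most damaging (NaN preserved)."""
    from .encode import rank_scale

    v = np.asarray(values, dtype=float)
    return rank_scale(v if higher_is_damaging else -v)


@dataclass
class RankByStateResult:
    """Per-state average scaled ranks and the two correlation summaries."""

    state_profiles: pd.DataFrame = field(default_factory=pd.DataFrame)
    leaderboard: pd.Series = field(default_factory=pd.Series)
    state_vs_leaderboard: pd.Series = field(default_factory=pd.Series)
    predictor_vs_dms: pd.Series = field(default_factory=pd.Series)


def rank_by_state(
    data: pd.DataFrame,
    predictor_cols: list[str],
    dms_col: str = "value",
    protein_col: str = "protein",
    leaderboard: pd.Series | None = None,
    higher_is_damaging: bool = False,
) -> RankByStateResult:
    """Average scaled ranks per state for predictors and DMS, with correlations.

    DMS values are rank-scaled within each protein (proteins with fewer than
    2 variants are excluded with a log entry); predictor scores are
    rank-scaled across all proteins.  Both use 1 = most damaging; by the
    usual fitness-assay convention lower raw values are more damaging, so
    ``higher_is_damaging`` defaults to False.

    Returns per-state average ranks (one column per predictor plus "DMS"),
    the leaderboard (mean per-protein Spearman of each predictor's damage
    ranks vs the DMS damage ranks, unless supplied), the Spearman of each
    state's predictor-rank profile against leaderboard performance, and each
    predictor's state-profile Spearman against the DMS state profile.
    """
    df = data.copy()
    sizes = df.groupby(protein_col)[dms_col].transform("size")
    small = sizes < 2
    if small.any():
        for p in df.loc[small, protein_col].unique():
            logger.info("protein %s has < 2 variants; excluded from DMS ranking", p)
        df = df[~small]

    df["_dms_rank"] = df.groupby(protein_col)[dms_col].transform(
        lambda v: _scaled_damage_rank(v.to_numpy(), higher_is_damaging)
    )
    rank_cols = {}
    for c in predictor_cols:
        rank_cols[c] = _scaled_damage_rank(
            pd.to_numeric(df[c], errors="coerce").to_numpy(), higher_is_damaging
        )
    ranks = pd.DataFrame(rank_cols, index=df.index)
    ranks["DMS"] = df["_dms_rank"]
    ranks["state"] = df["state"].to_numpy()

    profiles = ranks.groupby("state").mean()
    profiles.index.name = "state"

    if leaderboard is None:
        per_pred = {}
        for c in predictor_cols:
            cors = []
            for _, sub in df.groupby(protein_col):
                r = ranks.loc[sub.index]
                ok = ~(r[c].isna() | r["DMS"].isna())
                if ok.sum() >= 2:
                    cors.append(spearmanr(r.loc[ok, c], r.loc[ok, "DMS"]).statistic)
            per_pred[c] = float(np.nanmean(cors)) if cors else np.nan
        leaderboard = pd.Series(per_pred, name="performance")

    state_vs_leaderboard = pd.Series(
        {
            s: float(
                spearmanr(
                    profiles.loc[s, predictor_cols].to_numpy(),
                    leaderboard[predictor_cols].to_numpy(),
                ).statistic
            )
            for s in profiles.index
        },
        name="spearman_vs_leaderboard",
    )
    predictor_vs_dms = pd.Series(
        {
            c: float(
                spearmanr(
                    profiles[c].to_numpy(), profiles["DMS"].to_numpy()
                ).statistic
            )
            for c in predictor_cols
        },
        name="spearman_vs_dms_profile",
    )
    return RankByStateResult(
        state_profiles=profiles,
        leaderboard=leaderboard,
        state_vs_leaderboard=state_vs_leaderboard,
        predictor_vs_dms=predictor_vs_dms,
    )
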