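"""Self-contained synthetic fixtures with known ground truth.

Generates an HMM with separable emission profiles, samples per-gene state
paths and variant tables whose continuous scores are consistent with the
binarization rule by construction (present/absent scores live in disjoint
uniform bands split at 1 - Q/100), plus interval annotations with a designed
enrichment target and labeled / DMS-style tables with per-state effects for
the evaluation module.  Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .hmm import HmmModel

__all__ = [
    "SimulationConfig",
    "EffectConfig",
    "SyntheticDataset",
    "LabelsAndDms",
    "MatchResult",
    "simulate_model",
    "simulate_dataset",
    "simulate_intervals",
    "simulate_labels_and_dms",
    "match_states",
]

_BASES = np.array(list("ACGT"))
_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Stated world for the default fixture.

    Defaults are the scales used throughout the test suite: a 4-state,
    8-score model over 300 genes of 80 variant positions each, sticky
    transitions (0.7 diagonal mass), 10% missing scores and a top-10%
    binarization — small enough to train in seconds, large enough for
    parameter recovery within 0.05.
    """

    seed: int
    K: int = 4
    M: int = 8
    n_genes: int = 300
    positions_per_gene: int = 80
    alts_per_position: int = 1
    transition_stickiness: float = 0.7
    missing_rate: float = 0.1
    Q: float = 10.0

    def __post_init__(self) -> None:
        if not 1 <= self.alts_per_position <= 3:
            raise ValueError("alts_per_position must be in {1, 2, 3}")
        if not 0 < self.transition_stickiness < 1:
            raise ValueError("transition_stickiness must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 < self.Q < 100:
            raise ValueError("Q must lie strictly between 0 and 100")


@dataclass
class SyntheticDataset:
    """A simulated variant table with its ground truth.

    ``band_threshold`` is the designed present/absent score boundary
    (1 - Q/100): ``binarize(table, threshold=band_threshold)`` reproduces
    ``codes`` exactly on non-missing cells.
    """

    table: pd.DataFrame
    true_states: np.ndarray  # 1-based, aligned to table rows
    codes: np.ndarray  # ternary, aligned to table rows
    band_threshold: float
    model: HmmModel


def simulate_model(config: SimulationConfig) -> HmmModel:
    """Ground-truth model with separable per-state emission profiles.

    Each state owns the features congruent to it modulo K at
    present-probability ~0.8, carries a few random extra features at an
    intermediate level (~0.4, so profiles overlap without collapsing into one
    another), and sits near 0.05 elsewhere.  The transition matrix has
    ``transition_stickiness`` on the diagonal and the remainder spread
    uniformly; the initial distribution is uniform.
    """
    rng = np.random.default_rng(config.seed)
    K, M = config.K, config.M
    emission = np.empty((K, M))
    for s in range(K):
        owned = (np.arange(M) % K) == s
        extra = ~owned & (rng.random(M) < 0.1)
        emission[s] = np.where(
            owned,
            rng.uniform(0.75, 0.85, M),
            np.where(extra, rng.uniform(0.35, 0.45, M), rng.uniform(0.02, 0.08, M)),
        )
    stick = config.transition_stickiness
    if K == 1:
        transition = np.ones((1, 1))
    else:
        transition = np.full((K, K), (1.0 - stick) / (K - 1))
        np.fill_diagonal(transition, stick)
    initial = np.full(K, 1.0 / K)
    return HmmModel(initial, transition, emission)


def simulate_dataset(model: HmmModel, config: SimulationConfig) -> SyntheticDataset:
    """Variant table, ternary codes and true states sampled from the model.

    Per gene a state path is drawn from the Markov chain (one state per
    position, shared by that position's alternate-allele rows); per variant
    row and feature a present/absent bit is drawn from the state's Bernoulli
    parameter, then a continuous score is placed uniformly in the top band
    [1 - Q/100, 1] for bit 1 or the bottom band [0, 1 - Q/100) for bit 0.
    Missing cells (rate ``missing_rate``) have NaN scores and code 2.
    """
    rng = np.random.default_rng(config.seed + 1)
    K, M = model.emission.shape
    thr = 1.0 - config.Q / 100.0

    rows = []
    states_per_row: list[int] = []
    for g in range(config.n_genes):
        gene = f"gene{g:04d}"
        chrom = f"chr{(g % 22) + 1}"
        start = 1_000_000 + (g // 22) * 100_000
        positions = start + 3 * np.arange(config.positions_per_gene)
        path = np.empty(config.positions_per_gene, dtype=int)
        path[0] = rng.choice(K, p=model.initial)
        for t in range(1, len(path)):
            path[t] = rng.choice(K, p=model.transition[path[t - 1]])
        for t, pos in enumerate(positions):
            ref = rng.choice(_BASES)
            alts = rng.choice(
                [b for b in _BASES if b != ref],
                size=config.alts_per_position,
                replace=False,
            )
            for alt in alts:
                rows.append(
                    (
                        chrom,
                        int(pos),
                        str(ref),
                        str(alt),
                        gene,
                        str(rng.choice(_AMINO)),
                        str(rng.choice(_AMINO)),
                    )
                )
                states_per_row.append(int(path[t]))

    n = len(rows)
    true_states = np.asarray(states_per_row)
    p = model.emission[true_states]  # (n, M)
    bits = (rng.random((n, M)) < p).astype(np.int8)
    width_top = config.Q / 100.0
    scores = np.where(
        bits == 1,
        thr + rng.random((n, M)) * width_top,
        rng.random((n, M)) * thr,
    )
    missing = rng.random((n, M)) < config.missing_rate
    codes = np.where(missing, 2, bits).astype(np.int8)
    scores = np.where(missing, np.nan, scores)

    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gene", "aaref", "aaalt"]
    )
    for m in range(M):
        table[f"score{m:02d}"] = scores[:, m]
    return SyntheticDataset(
        table=table,
        true_states=true_states + 1,
        codes=codes,
        band_threshold=thr,
        model=model,
    )


def simulate_intervals(
    table: pd.DataFrame,
    true_states: np.ndarray,
    state: int,
    p_in: float = 1.0,
    p_out: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """BED intervals marking the footprint of one state, plus optional noise.

    Each variant position of the target state is covered with probability
    ``p_in`` and every other position with probability ``p_out`` (one-base
    intervals, 0-based half-open), giving a known expected fold enrichment
    for the target state.
    """
    rng = np.random.default_rng(seed)
    in_state = np.asarray(true_states) == state
    cover = np.where(in_state, rng.random(len(table)) < p_in, rng.random(len(table)) < p_out)
    sub = table.loc[cover, ["chrom", "pos"]].drop_duplicates()
    bed = pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "start": sub["pos"].to_numpy() - 1,
            "end": sub["pos"].to_numpy(),
        }
    )
    return bed.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class EffectConfig:
    """Per-state effects for label and DMS generation.

    Labels: P(positive) = logistic(a * score + b_state + b0).
    DMS:    value = c * score + d_state + Normal(0, noise_sd).
    """

    b_state: np.ndarray
    d_state: np.ndarray
    a: float = 3.0
    b0: float = -1.5
    c: float = 1.0
    noise_sd: float = 0.3


@dataclass
class LabelsAndDms:
    labels: np.ndarray  # 0/1 per table row
    dms: np.ndarray  # continuous per table row
    effects: EffectConfig = field(repr=False, default=None)


def simulate_labels_and_dms(
    table: pd.DataFrame,
    true_states: np.ndarray,
    effects: EffectConfig,
    seed: int = 0,
    score_col: str | None = None,
) -> LabelsAndDms:
    """Binary labels and DMS-style measurements with per-state offsets.

    ``score_col`` defaults to the table's first score column; missing score
    values are imputed at 0.5 for generation only.  Ground-truth effects are
    returned for recovery assertions.
    """
    from .encode import score_columns

    rng = np.random.default_rng(seed)
    if score_col is None:
        score_col = score_columns(table)[0]
    score = pd.to_numeric(table[score_col], errors="coerce").to_numpy(float)
    score = np.where(np.isnan(score), 0.5, score)
    s0 = np.asarray(true_states) - 1  # to 0-based
    b = np.asarray(effects.b_state)[s0]
    d = np.asarray(effects.d_state)[s0]
    logit = effects.a * score + b + effects.b0
    p = 1.0 / (1.0 + np.exp(-logit))
    labels = (rng.random(len(p)) < p).astype(int)
    dms = effects.c * score + d + rng.normal(0.0, effects.noise_sd, len(p))
    return LabelsAndDms(labels=labels, dms=dms, effects=effects)


@dataclass
class MatchResult:
    """Hungarian matching of estimated states to true states.

    ``permutation[i]`` is the estimated-state index matched to true state i
    (0-based).  Errors are mean absolute parameter differences under the
    matching.
    """

    permutation: np.ndarray
    mean_emission_error: float
    mean_transition_error: float
    per_state_emission_error: np.ndarray


def match_states(true_model: HmmModel, est_model: HmmModel) -> MatchResult:
    """Optimal one-to-one state matching by emission-profile correlation."""
    if true_model.n_states != est_model.n_states:
        raise ValueError("models must have the same number of states")
    if true_model.n_features != est_model.n_features:
        raise ValueError("models must share the same number of features")
    et, ee = true_model.emission, est_model.emission
    tc = et - et.mean(axis=1, keepdims=True)
    ec = ee - ee.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (tc @ ec.T) / (
            np.linalg.norm(tc, axis=1)[:, None] * np.linalg.norm(ec, axis=1)[None, :]
        )
    corr = np.nan_to_num(corr, nan=0.0)
    _, perm = linear_sum_assignment(-corr)
    per_state = np.abs(et - ee[perm]).mean(axis=1)
    at = true_model.transition
    ae = est_model.transition[np.ix_(perm, perm)]
    return MatchResult(
        permutation=perm,
        mean_emission_error=float(per_state.mean()),
        mean_transition_error=float(np.abs(at - ae).mean()),
        per_state_emission_error=per_state,
    )
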