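"""Binarization of variant score tables into ternary HMM observations.

The variant table is a pandas DataFrame, dbNSFP-style: one row per missense
variant with columns ``chrom, pos, ref, alt, gene`` (optionally ``aaref,
aaalt``) and any number of score columns holding rank-scaled values in [0, 1]
(NaN = missing).  Per score, the top Q% of non-missing values are encoded 1
("present"), the remaining scored values 0, and missing values 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .hmm import ObservationSequence

logger = logging.getLogger(__name__)

__all__ = [
    "KEY_COLUMNS",
    "BinarizationConfig",
    "score_columns",
    "rank_scale",
    "qc_filter_scores",
    "binarize",
    "build_training_sequences",
]

#: identity / bookkeeping columns; everything else in a variant table is a score
KEY_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "aaref", "aaalt")


@dataclass
class BinarizationConfig:
    """Q: top-percent threshold; QC limits on missingness and max-value ties."""

    Q: float = 10.0
    missing_rate_max: float = 0.5
    top_tie_rate_max: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.Q < 100:
            raise ValueError("Q must lie strictly between 0 and 100")


def score_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a variant table that hold scores (everything non-key)."""
    return [c for c in table.columns if c not in KEY_COLUMNS]


def rank_scale(raw_scores) -> np.ndarray:
    """Rescale values to [0, 1] by rank, 1 = most damaging; NaN preserved.

    Non-missing values are replaced by (rank - 1) / (n - 1) using mean ranks
    for ties.  A single non-missing value maps to 0.5 (midpoint; the formula
    is undefined at n = 1).
    """
    values = np.asarray(raw_scores, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("rank_scale requires at least one non-missing value")
    if n == 1:
        out[mask] = 0.5
        return out
    ranks = rankdata(values[mask], method="average")
    out[mask] = (ranks - 1.0) / (n - 1.0)
    return out


def qc_filter_scores(
    table: pd.DataFrame, config: BinarizationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop score columns failing missingness or max-value-tie QC.

    A score is dropped when its missing fraction exceeds
    ``config.missing_rate_max`` or when the fraction of its non-missing
    values tied at the maximum exceeds ``config.top_tie_rate_max`` (scores
    massed at the top carry no usable top-Q% signal).

    Returns the filtered table and a report with one row per dropped score
    (``score``, ``reason``, ``statistic``).
    """
    if config is None:
        config = BinarizationConfig()
    dropped: list[dict] = []
    keep: list[str] = []
    for col in score_columns(table):
        values = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
        n = len(values)
        missing_rate = float(np.isnan(values).sum()) / n if n else 0.0
        if missing_rate > config.missing_rate_max:
            dropped.append(
                {"score": col, "reason": "missing_rate", "statistic": missing_rate}
            )
            continue
        nonmiss = values[~np.isnan(values)]
        tie_rate = (
            float((nonmiss == nonmiss.max()).sum()) / len(nonmiss)
            if len(nonmiss)
            else 1.0
        )
        if tie_rate > config.top_tie_rate_max:
            dropped.append(
                {"score": col, "reason": "top_tie_rate", "statistic": tie_rate}
            )
            continue
        keep.append(col)
    if not keep:
        raise ValueError("all score columns were dropped by QC")
    report = pd.DataFrame(dropped, columns=["score", "reason", "statistic"])
    kept_cols = [c for c in table.columns if c in KEY_COLUMNS or c in keep]
    return table[kept_cols].copy(), report


def _top_q_codes(values: np.ndarray, Q: float) -> np.ndarray:
    """Ternary codes for one score column with the top-Q% order-statistic rule.

    The cutoff is the ceil(Q% * n)-th largest non-missing value; every value
    >= cutoff is coded 1, so ties at the cutoff (in particular a mass tied at
    the maximum exceeding Q%) are all coded 1.
    """
    codes = np.full(values.shape, 2, dtype=np.int8)
    mask = ~np.isnan(values)
    nonmiss = values[mask]
    n = len(nonmiss)
    if n == 0:
        return codes
    k = max(1, math.ceil(Q / 100.0 * n))
    cutoff = np.partition(nonmiss, n - k)[n - k]
    codes[mask] = (values[mask] >= cutoff).astype(np.int8)
    return codes


def binarize(
    table: pd.DataFrame,
    config: BinarizationConfig | None = None,
    threshold: float | dict | None = None,
) -> np.ndarray:
    """Ternary code matrix (one row per variant, one column per score).

    Per column: 1 if the value falls in the top Q% of non-missing values
    (cutoff = the ceil(Q%*n)-th largest value, >=-inclusive so over-Q% masses
    tied at the maximum are all 1), 0 for other non-missing values, 2 for
    missing.  If ``threshold`` is given (a scalar, or a mapping from score
    name to value), the quantile rule is bypassed and values >= threshold are
    coded 1 — used when the present/absent boundary is known externally, e.g.
    for synthetic data with a designed band split.
    """
    if config is None:
        config = BinarizationConfig()
    cols = score_columns(table)
    out = np.empty((len(table), len(cols)), dtype=np.int8)
    for j, col in enumerate(cols):
        values = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
        if threshold is None:
            out[:, j] = _top_q_codes(values, config.Q)
        else:
            thr = threshold[col] if isinstance(threshold, dict) else float(threshold)
            codes = np.full(values.shape, 2, dtype=np.int8)
            mask = ~np.isnan(values)
            codes[mask] = (values[mask] >= thr).astype(np.int8)
            out[:, j] = codes
    return out


def build_training_sequences(
    table: pd.DataFrame, codes: np.ndarray, seed: int = 0
) -> tuple[dict[str, ObservationSequence], pd.DataFrame]:
    """One training sequence per gene: one random variant per unique position.

    For each gene, positions are sorted ascending and at each position one
    variant row is chosen uniformly at random with the seeded RNG (genes are
    processed in sorted-name order, so the draws are reproducible).  Returns
    ``{gene: ObservationSequence}`` and a manifest DataFrame mapping each
    sequence position to the chosen table row index (``gene, pos, row``).
    """
    if len(codes) != len(table):
        raise ValueError("codes must align with the table rows")
    rng = np.random.default_rng(seed)
    sequences: dict[str, ObservationSequence] = {}
    manifest_rows: list[tuple] = []
    positions = table["pos"].to_numpy()
    row_index = np.arange(len(table))
    for gene in sorted(table["gene"].astype(str).unique()):
        in_gene = (table["gene"].astype(str) == gene).to_numpy()
        if not in_gene.any():
            logger.info("gene %s has no variants; skipped", gene)
            continue
        gene_rows = row_index[in_gene]
        gene_pos = positions[in_gene]
        chosen: list[int] = []
        for pos in np.unique(gene_pos):
            candidates = gene_rows[gene_pos == pos]
            pick = candidates[rng.integers(len(candidates))] if len(candidates) > 1 else candidates[0]
            chosen.append(int(pick))
            manifest_rows.append((gene, int(pos), int(pick)))
        sequences[gene] = ObservationSequence(codes[chosen])
    manifest = pd.DataFrame(manifest_rows, columns=["gene", "pos", "row"])
    return sequences, manifest
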