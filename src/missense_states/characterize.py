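"""State-level characterization: emission summaries, enrichments, substitutions.

Fold enrichment of a state for an interval annotation follows the standard
contingency ratio (B_sa / B_s) / (B_a / B_total): the annotation frequency
among the state's variants over the annotation frequency in the background
set of variants.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .hmm import HmmModel

__all__ = [
    "summarize_states",
    "fold_enrichment",
    "substitution_preferences",
    "compare_models",
]


def summarize_states(
    model: HmmModel,
    group_thresholds: tuple[int, int] | None = None,
    top_n: int = 5,
) -> pd.DataFrame:
    """Rank-based summary of each state's emission profile.

    For every score the states are ranked by emission probability in
    descending order (ties share the minimum rank); a state's ``top5_count``
    is the number of scores for which it ranks within the top ``top_n``.
    States are displayed in descending top5_count order (ties toward the
    lower state index) and cut into four groups by lower bounds on the
    count: group 1 >= t1, group 2 >= t2, group 3 >= 1, group 4 = 0.  The
    default thresholds (t1, t2) = (ceil(0.8*M), ceil(0.15*M)) generalize the
    empirical cuts used at M = 43 (35 and 7).
    """
    K, M = model.emission.shape
    if group_thresholds is None:
        group_thresholds = (math.ceil(0.8 * M), math.ceil(0.15 * M))
    t1, t2 = group_thresholds

    e = model.emission
    # rank of state s for score m: 1 + number of states with strictly larger emission
    ranks = 1 + (e[None, :, :] > e[:, None, :]).sum(axis=1)  # (K, M)
    top_counts = (ranks <= top_n).sum(axis=1)

    display = np.lexsort((np.arange(K), -top_counts))
    display_order = np.empty(K, dtype=int)
    display_order[display] = np.arange(1, K + 1)

    groups = np.where(
        top_counts >= t1, 1, np.where(top_counts >= t2, 2, np.where(top_counts >= 1, 3, 4))
    )
    return pd.DataFrame(
        {
            "state": np.arange(1, K + 1),
            "top5_count": top_counts,
            "display_order": display_order,
            "group": groups,
        }
    )


def _overlap_mask(
    chroms: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """True where a 1-based variant position falls inside a 0-based half-open interval."""
    if (intervals["start"] >= intervals["end"]).any():
        raise ValueError("malformed interval: start >= end")
    hit = np.zeros(len(pos), dtype=bool)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sel = chroms == str(chrom)
        if not sel.any():
            continue
        # merge overlapping intervals so searchsorted gives a unique bucket
        sub = sub.sort_values("start")
        starts, ends = [], []
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        starts_a = np.asarray(starts)
        ends_a = np.asarray(ends)
        p0 = pos[sel] - 1  # convert 1-based position to 0-based coordinate
        idx = np.searchsorted(starts_a, p0, side="right") - 1
        ok = (idx >= 0) & (p0 < ends_a[np.clip(idx, 0, None)])
        hit[sel] = ok
    return hit


def fold_enrichment(
    assignments: pd.DataFrame,
    intervals: pd.DataFrame | dict[str, pd.DataFrame],
    background: pd.DataFrame | None = None,
    unique_positions: bool = False,
) -> pd.DataFrame:
    """Per-state fold enrichment of variants for interval annotations.

    ``intervals`` is a BED-style DataFrame (chrom, start, end; 0-based
    half-open) or a dict mapping annotation names to such frames.
    ``background`` defaults to the assignment table itself (all variants as
    background), which is what makes the count identities
    sum_s B_sa = B_a and sum_s B_s = B_total hold.  ``unique_positions``
    counts each (chrom, pos) once instead of every alternate-allele row.

    Fold is NaN when B_s = 0 or B_a = 0 and 0.0 when only B_sa = 0.
    """
    if isinstance(intervals, pd.DataFrame):
        intervals = {"annotation": intervals}
    if background is None:
        background = assignments
    df = assignments
    bg = background
    if unique_positions:
        df = df.drop_duplicates(subset=["chrom", "pos"])
        bg = bg.drop_duplicates(subset=["chrom", "pos"])

    chroms = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy()
    bg_chroms = bg["chrom"].astype(str).to_numpy()
    bg_pos = bg["pos"].to_numpy()
    states = df["state"].to_numpy()
    all_states = np.unique(states)
    b_total = len(bg)

    rows = []
    for name, ivals in intervals.items():
        in_a = _overlap_mask(chroms, pos, ivals)
        b_a = int(_overlap_mask(bg_chroms, bg_pos, ivals).sum())
        for s in all_states:
            in_s = states == s
            b_s = int(in_s.sum())
            b_sa = int((in_s & in_a).sum())
            if b_s == 0 or b_a == 0:
                fold = np.nan
            else:
                fold = (b_sa / b_s) / (b_a / b_total)
            rows.append(
                {
                    "state": int(s),
                    "annotation": name,
                    "B_sa": b_sa,
                    "B_s": b_s,
                    "B_a": b_a,
                    "B_total": b_total,
                    "fold": fold,
                }
            )
    return pd.DataFrame(rows)


def substitution_preferences(
    assignments: pd.DataFrame, table: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Per-state amino-acid substitution preferences vs the overall composition.

    Joins assignments with the variant table on (chrom, pos, ref, alt) to get
    aaref/aaalt, then per state and ordered substitution X->Y reports the
    count, the proportion among the state's variants, the overall proportion
    across all states, their difference (``delta``) and ratio (``fold``).
    Rows with missing amino acids are excluded; their count is returned.
    """
    key = ["chrom", "pos", "ref", "alt"]
    cols = key + ["aaref", "aaalt"]
    if "aaref" not in table.columns or "aaalt" not in table.columns:
        raise ValueError("variant table lacks aaref/aaalt columns")
    merged = assignments.merge(table[cols], on=key, how="left")
    missing = merged["aaref"].isna() | merged["aaalt"].isna()
    n_excluded = int(missing.sum())
    merged = merged[~missing].copy()
    merged["substitution"] = (
        merged["aaref"].astype(str) + ">" + merged["aaalt"].astype(str)
    )

    overall = merged["substitution"].value_counts(normalize=True)
    subs = overall.index.to_list()
    rows = []
    for state, sub in merged.groupby("state"):
        props = sub["substitution"].value_counts(normalize=True)
        counts = sub["substitution"].value_counts()
        for s in subs:
            p_state = float(props.get(s, 0.0))
            p_all = float(overall[s])
            rows.append(
                {
                    "state": int(state),
                    "substitution": s,
                    "count": int(counts.get(s, 0)),
                    "prop_state": p_state,
                    "prop_overall": p_all,
                    "delta": p_state - p_all,
                    "fold": p_state / p_all if p_all > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows), n_excluded


def compare_models(model_a: HmmModel, model_b: HmmModel) -> pd.DataFrame:
    """Best emission-profile correlation of each state of ``model_a`` in ``model_b``.

    Pearson correlation between emission vectors (length M); per state of a,
    the maximum over b's states and the 1-based index achieving it.  States
    with zero-variance emission vectors get NaN.
    """
    if model_a.n_features != model_b.n_features:
        raise ValueError("models must share the same number of features")
    ea, eb = model_a.emission, model_b.emission
    sa = ea.std(axis=1)
    sb = eb.std(axis=1)
    ac = ea - ea.mean(axis=1, keepdims=True)
    bc = eb - eb.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (ac @ bc.T) / ea.shape[1] / np.outer(sa, sb)
    corr[~np.isfinite(corr)] = np.nan
    best = np.full(ea.shape[0], np.nan)
    match = np.zeros(ea.shape[0], dtype=int)
    for i in range(ea.shape[0]):
        row = corr[i]
        if np.isnan(row).all():
            continue
        j = int(np.nanargmax(row))
        best[i] = row[j]
        match[i] = j + 1
    return pd.DataFrame(
        {
            "state": np.arange(1, ea.shape[0] + 1),
            "best_correlation": best,
            "best_match": match,
        }
    )
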