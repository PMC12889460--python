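"""State assignment of variants via local window combinations and the mode rule.

Enumerating every possible per-position variant choice in a gene is
exponential, so each target variant is assigned by sampling N "local
combinations": sequences over a window of k positions on either side of the
target (truncated at gene ends, never crossing gene boundaries) where the
target's own row is fixed and one variant is drawn uniformly at random per
flanking position.  Forward-backward posterior decoding gives a state per
combination at the target's position; the final call is the mode over the N
combinations, ties broken uniformly at random.

Also provides the uniform-transition counterpart model (isolating the
contribution of spatial context), run-length segmentation of assignments, and
the statistics comparing two assignments (per-state switch fractions and a
one-sided Mann-Whitney U on segment lengths).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .hmm import (
    HmmModel,
    ObservationSequence,
    _forward_backward_batch,
)

__all__ = [
    "AnnotationConfig",
    "local_combinations",
    "assign_state",
    "annotate_all",
    "uniformize_transitions",
    "segment_assignments",
    "compare_assignments",
]

_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class AnnotationConfig:
    """k flanking positions per side, N local combinations, RNG seed."""

    k: int = 3
    N: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")


def uniformize_transitions(model: HmmModel) -> HmmModel:
    """Copy of the model with every transition probability set to 1/K."""
    K = model.n_states
    return HmmModel(
        model.initial.copy(),
        np.full((K, K), 1.0 / K),
        model.emission.copy(),
    )


class _GeneIndex:
    """Per-gene position structure: sorted unique positions and the table rows at each."""

    def __init__(self, table: pd.DataFrame):
        self.rows_by_gene: dict[str, tuple[np.ndarray, list[np.ndarray]]] = {}
        genes = table["gene"].astype(str).to_numpy()
        pos = table["pos"].to_numpy()
        order = np.arange(len(table))
        for gene in sorted(pd.unique(genes)):
            sel = order[genes == gene]
            gpos = pos[sel]
            uniq = np.unique(gpos)
            rows = [sel[gpos == p] for p in uniq]
            self.rows_by_gene[gene] = (uniq, rows)


def _window_combinations(
    uniq_pos: np.ndarray,
    rows: list[np.ndarray],
    pos_idx: int,
    target_row: int,
    config: AnnotationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """N stacked row-index windows around one target.

    Returns ``(choices, center)`` where choices has shape (N, T_window) of
    table row indices and ``center`` is the target's index in the window.
    """
    lo = max(0, pos_idx - config.k)
    hi = min(len(uniq_pos) - 1, pos_idx + config.k)
    width = hi - lo + 1
    center = pos_idx - lo
    choices = np.empty((config.N, width), dtype=np.int64)
    for j, p in enumerate(range(lo, hi + 1)):
        cand = rows[p]
        if p == pos_idx:
            choices[:, j] = target_row
        elif len(cand) == 1:
            choices[:, j] = cand[0]
        else:
            choices[:, j] = cand[rng.integers(0, len(cand), size=config.N)]
    return choices, center


def local_combinations(
    table: pd.DataFrame,
    codes: np.ndarray,
    target,
    config: AnnotationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ObservationSequence], list[int]]:
    """N window sequences around a target variant plus the center index of each.

    ``target`` is a (chrom, pos, ref, alt) tuple.  The window spans up to k
    positions up- and downstream of the target within its gene (truncated at
    gene ends); the target's own row is fixed in every combination while each
    flanking position's variant is drawn uniformly at random.
    """
    if config is None:
        config = AnnotationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom, pos, ref, alt = target
    mask = (
        (table["chrom"].astype(str) == str(chrom))
        & (table["pos"] == pos)
        & (table["ref"].astype(str) == str(ref))
        & (table["alt"].astype(str) == str(alt))
    )
    hits = np.flatnonzero(mask.to_numpy())
    if len(hits) == 0:
        raise KeyError(f"target variant {target} not found in table")
    target_row = int(hits[0])
    gene = str(table["gene"].iloc[target_row])
    index = _GeneIndex(table)
    uniq_pos, rows = index.rows_by_gene[gene]
    pos_idx = int(np.searchsorted(uniq_pos, pos))
    choices, center = _window_combinations(
        uniq_pos, rows, pos_idx, target_row, config, rng
    )
    seqs = [ObservationSequence(codes[c]) for c in choices]
    return seqs, [center] * len(seqs)


def assign_state(
    model: HmmModel,
    table: pd.DataFrame,
    codes: np.ndarray,
    target,
    config: AnnotationConfig | None = None,
) -> dict:
    """Mode state assignment for one target variant.

    Per combination the state is the argmax of the forward-backward posterior
    at the target's window position (argmax ties go to the lowest state
    index); the final state is the mode over combinations with mode ties
    broken uniformly at random.  States are reported 1-based.
    """
    if config is None:
        config = AnnotationConfig()
    rng_flank, rng_tie = np.random.default_rng(config.seed).spawn(2)
    seqs, centers = local_combinations(table, codes, target, config, rng_flank)
    votes = np.empty(len(seqs), dtype=np.int64)
    for i, (seq, c) in enumerate(zip(seqs, centers)):
        gamma, _, _, _ = _forward_backward_batch(model, seq.codes[None])
        votes[i] = int(np.argmax(gamma[0, c]))
    return _mode_vote(votes, model.n_states, rng_tie)


def _mode_vote(votes: np.ndarray, K: int, rng: np.random.Generator) -> dict:
    counts = np.bincount(votes, minlength=K)
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    tie_broken = len(tied) > 1
    state = int(tied[rng.integers(len(tied))]) if tie_broken else int(tied[0])
    return {
        "state": state + 1,
        "n_mode_votes": int(top),
        "tie_broken": bool(tie_broken),
    }


def annotate_all(
    model: HmmModel,
    table: pd.DataFrame,
    codes: np.ndarray,
    config: AnnotationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign a state to every variant row; return assignments and segmentation.

    All variant rows are annotated (not the one-per-position training sample).
    Deterministic for a fixed ``config.seed``: the seeded RNG is split into a
    flank-sampling stream and a tie-breaking stream; variants are processed in
    (gene, pos, ref, alt) order.

    Returns (assignments, segments): assignments carries chrom, pos, ref,
    alt, gene, state (1-based), n_mode_votes, tie_broken; segments is the
    run-length segmentation from :func:`segment_assignments`.
    """
    if config is None:
        config = AnnotationConfig()
    rng_flank, rng_tie = np.random.default_rng(config.seed).spawn(2)

    work = table.reset_index(drop=True)
    order = work.sort_values(
        ["gene", "pos", "ref", "alt"], kind="mergesort"
    ).index.to_numpy()
    index = _GeneIndex(work)

    # First pass: build all (variant, combination) windows, bucketed by window
    # width so forward-backward runs vectorized on equal-length batches.
    buckets: dict[int, list[np.ndarray]] = {}
    bucket_meta: dict[int, list[tuple[int, int]]] = {}  # (variant slot, center)
    genes = work["gene"].astype(str).to_numpy()
    pos_arr = work["pos"].to_numpy()
    for slot, row in enumerate(order):
        uniq_pos, rows = index.rows_by_gene[genes[row]]
        pos_idx = int(np.searchsorted(uniq_pos, pos_arr[row]))
        choices, center = _window_combinations(
            uniq_pos, rows, pos_idx, int(row), config, rng_flank
        )
        width = choices.shape[1]
        buckets.setdefault(width, []).append(choices)
        bucket_meta.setdefault(width, []).extend(
            (slot, center) for _ in range(config.N)
        )

    n = len(work)
    votes = np.empty((n, config.N), dtype=np.int64)
    fill = np.zeros(n, dtype=np.int64)
    for width, chunks in buckets.items():
        row_windows = np.concatenate(chunks, axis=0)  # (B, width)
        batch_codes = codes[row_windows]  # (B, width, M)
        gamma, _, _, _ = _forward_backward_batch(model, batch_codes)
        meta = bucket_meta[width]
        centers = np.array([c for _, c in meta])
        states = np.argmax(gamma[np.arange(len(meta)), centers, :], axis=1)
        for (slot, _), st in zip(meta, states):
            votes[slot, fill[slot]] = st
            fill[slot] += 1

    results = [
        _mode_vote(votes[slot], model.n_states, rng_tie) for slot in range(n)
    ]
    ordered = work.loc[order, ["chrom", "pos", "ref", "alt", "gene"]].reset_index(
        drop=True
    )
    ordered["state"] = [r["state"] for r in results]
    ordered["n_mode_votes"] = [r["n_mode_votes"] for r in results]
    ordered["tie_broken"] = [r["tie_broken"] for r in results]
    segments = segment_assignments(ordered)
    return ordered, segments


def segment_assignments(
    assignments: pd.DataFrame, per_position: bool = False
) -> pd.DataFrame:
    """Run-length segmentation of state assignments within each gene.

    Variants are ordered by (gene, pos, ref, alt); maximal runs of identical
    states form segments.  With ``per_position=True`` only the first variant
    row at each (gene, pos) enters the run sequence (one call per position);
    the default counts every annotated row.
    """
    df = assignments.sort_values(["gene", "pos", "ref", "alt"], kind="mergesort")
    if per_position:
        df = df.drop_duplicates(subset=["gene", "pos"], keep="first")
    out = []
    for gene, sub in df.groupby("gene", sort=True):
        states = sub["state"].to_numpy()
        change = np.flatnonzero(np.diff(states) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change, [len(states) - 1]])
        for s, e in zip(starts, ends):
            out.append(
                {
                    "gene": gene,
                    "start": int(s),
                    "end": int(e),
                    "state": int(states[s]),
                    "length": int(e - s + 1),
                }
            )
    return pd.DataFrame(out, columns=["gene", "start", "end", "state", "length"])


def compare_assignments(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Agreement statistics between two assignments of the same variants.

    For each state of ``a``, the fraction of its variants assigned a
    different state in ``b``; the overall mean switch fraction; segment
    counts and mean lengths for both segmentations; and a one-sided
    Mann-Whitney U testing whether ``a``'s segment lengths are stochastically
    larger than ``b``'s.
    """
    key = _KEY + ["gene"]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"), validate="one_to_one")
    if len(merged) != len(a) or len(merged) != len(b):
        raise ValueError("assignment tables must cover the same variant keys")
    switched = merged["state_a"] != merged["state_b"]
    per_state = switched.groupby(merged["state_a"]).mean()
    per_state.index.name = "state"

    seg_a = segment_assignments(a)
    seg_b = segment_assignments(b)
    if len(seg_a) and len(seg_b):
        stat, pvalue = mannwhitneyu(
            seg_a["length"], seg_b["length"], alternative="greater"
        )
    else:
        stat, pvalue = np.nan, np.nan
    return {
        "per_state_switch_fraction": per_state,
        "mean_switch_fraction": float(switched.mean()),
        "n_segments_a": int(len(seg_a)),
        "n_segments_b": int(len(seg_b)),
        "mean_segment_length_a": float(seg_a["length"].mean()) if len(seg_a) else np.nan,
        "mean_segment_length_b": float(seg_b["length"].mean()) if len(seg_b) else np.nan,
        "mannwhitney_u": float(stat),
        "mannwhitney_p": float(pvalue),
    }
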