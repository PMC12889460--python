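"""Plain-text readers and writers for every interchange format.

Conventions: variant tables are tab-separated with 1-based positions and
"." or empty cells for missing scores (dbNSFP-style); BED intervals are
0-based half-open; model files are a small text format with a "K M" header
and tab-separated initial/transition/emission blocks at 6 significant
digits.  Each writer has a reader and round-trips are tested.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .encode import score_columns
from .hmm import HmmModel, ObservationSequence

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "read_bed",
    "write_bed",
    "read_model",
    "write_model",
    "read_codes",
    "write_codes",
    "read_assignments",
    "write_assignments",
    "assignments_to_bed",
    "RunConfig",
]

_REQUIRED = ("chrom", "pos", "ref", "alt", "gene")


def variant_pos_to_bed(pos: int) -> tuple[int, int]:
    """Central 1-based -> 0-based half-open conversion for a single base."""
    return pos - 1, pos


def read_variant_table(path) -> pd.DataFrame:
    """Read a dbNSFP-style tab-separated variant score table.

    Required columns: chrom, pos (1-based), ref, alt, gene; optional aaref,
    aaalt; all remaining columns are scores. "." or empty cells are missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    df = df.replace("", np.nan)
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    df["pos"] = df["pos"].astype(int)
    for col in score_columns(df):
        try:
            df[col] = df[col].astype(float)
        except ValueError:
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() & df[col].notna())[0]) + 1
            raise ValueError(
                f"non-numeric value in score column {col!r} at data row {row}"
            ) from None
    return df


def write_variant_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ intervals (0-based half-open), validated and sorted per chromosome."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {i}: BED requires at least 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"line {i}: start >= end ({start} >= {end})")
            row = {"chrom": chrom, "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (
        ["name"] if "name" in intervals.columns else []
    )
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def write_model(model: HmmModel, path) -> None:
    """Text model file: 'K M' header, then initial/transition/emission blocks."""
    with open(path, "w") as fh:
        fh.write(f"{model.n_states}\t{model.n_features}\n")
        fh.write("initial\n")
        fh.write("\t".join(f"{x:.6g}" for x in model.initial) + "\n")
        fh.write("transition\n")
        for row in model.transition:
            fh.write("\t".join(f"{x:.6g}" for x in row) + "\n")
        fh.write("emission\n")
        for row in model.emission:
            fh.write("\t".join(f"{x:.6g}" for x in row) + "\n")


def read_model(path) -> HmmModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    K, M = (int(x) for x in lines[0].split("\t"))
    if lines[1] != "initial" or lines[3] != "transition" or lines[4 + K] != "emission":
        raise ValueError("malformed model file")
    initial = np.array([float(x) for x in lines[2].split("\t")])
    transition = np.array(
        [[float(x) for x in lines[4 + i].split("\t")] for i in range(K)]
    )
    emission = np.array(
        [[float(x) for x in lines[5 + K + i].split("\t")] for i in range(K)]
    )
    # renormalize the 6-significant-digit rounding so invariants hold exactly
    initial = initial / initial.sum()
    transition = transition / transition.sum(axis=1, keepdims=True)
    model = HmmModel(initial, transition, emission)
    if model.n_features != M:
        raise ValueError("model file header disagrees with emission block")
    return model


def write_codes(sequences: dict[str, ObservationSequence], directory) -> None:
    """One tab-separated ternary code file per gene (gene name in the filename)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for gene, seq in sequences.items():
        np.savetxt(
            directory / f"{gene}_codes.tsv", seq.codes, fmt="%d", delimiter="\t"
        )


def read_codes(directory) -> dict[str, ObservationSequence]:
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob("*_codes.tsv")):
        gene = path.name[: -len("_codes.tsv")]
        codes = np.loadtxt(path, dtype=np.int8, delimiter="\t", ndmin=2)
        out[gene] = ObservationSequence(codes)
    return out


def write_assignments(assignments: pd.DataFrame, path) -> None:
    assignments.to_csv(path, sep="\t", index=False)


def read_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    df["pos"] = df["pos"].astype(int)
    df["state"] = df["state"].astype(int)
    return df


def assignments_to_bed(assignments: pd.DataFrame) -> pd.DataFrame:
    """Single-nucleotide BED intervals with the state label in the name field."""
    return pd.DataFrame(
        {
            "chrom": assignments["chrom"].to_numpy(),
            "start": assignments["pos"].to_numpy() - 1,
            "end": assignments["pos"].to_numpy(),
            "name": [f"state{s}" for s in assignments["state"]],
        }
    )


@dataclasses.dataclass
class RunConfig:
    """Single serializable configuration echoed into run logs.

    Round-trips losslessly through JSON; records the package version so every
    run is attributable to a configuration and code state.
    """

    Q: float = 10.0
    K: int = 4
    k: int = 3
    N: int = 9
    seed: int = 0
    n_subsample: int | str = "all"
    pseudocount: float = 1.0
    max_iterations: int = 200
    n_restarts: int = 3
    missing_rate_max: float = 0.5
    top_tie_rate_max: float = 0.5
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())
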