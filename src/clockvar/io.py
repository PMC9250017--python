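"""Reading and writing per-cell smFISH count tables and analysis results.

The canonical interchange format is delimited text (CSV or TSV) with the
exact header::

    embryo_id,genotype,half,slice_index,cell_id,her1_count,her7_count,volume

One row per segmented cell: absolute her1/her7 transcript counts from
single-molecule FISH, the cell volume in um^3, and the cell's position as a
0-based posterior-to-anterior slice index within the left or right half of
the presomitic mesoderm.  Supplementary spreadsheet exports with arbitrary
column layouts are mapped onto this schema via a user-supplied column
mapping (:func:`import_mapped_table`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, SchemaError, ValidationError
from .variability import BinnedCurve

__all__ = [
    "CellRecord",
    "CellTable",
    "read_cell_table",
    "write_cell_table",
    "import_mapped_table",
    "write_results",
    "read_results",
]

#: Canonical column order of a cell table.
COLUMNS = [
    "embryo_id",
    "genotype",
    "half",
    "slice_index",
    "cell_id",
    "her1_count",
    "her7_count",
    "volume",
]

_HALVES = ("left", "right")


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: transcript counts, volume and slice position."""

    embryo_id: str
    genotype: str
    half: str  # "left" | "right"
    slice_index: int  # 0 = most posterior
    cell_id: str
    her1_count: int
    her7_count: int
    volume: float  # um^3


class CellTable:
    """A validated table of :class:`CellRecord` rows (pandas-backed).

    Counts are non-negative, volumes strictly positive, and
    (embryo_id, half, slice_index, cell_id) is unique.  Counts may be
    real-valued after volume correction; raw tables hold integers.
    """

    def __init__(self, df: pd.DataFrame, provenance: dict | None = None,
                 validate: bool = True):
        if validate:
            df = _validate(df)
        self.df = df.reset_index(drop=True)
        self.provenance = provenance or {}

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CellTable):
            return NotImplemented
        return self.df[COLUMNS].equals(other.df[COLUMNS])

    @property
    def records(self) -> Iterator[CellRecord]:
        for row in self.df.itertuples(index=False):
            yield CellRecord(
                embryo_id=row.embryo_id, genotype=row.genotype, half=row.half,
                slice_index=int(row.slice_index), cell_id=row.cell_id,
                her1_count=row.her1_count, her7_count=row.her7_count,
                volume=float(row.volume),
            )

    def genotypes(self) -> list[str]:
        return sorted(self.df["genotype"].unique())

    def select(self, genotype: str) -> "CellTable":
        sub = self.df[self.df["genotype"] == genotype]
        if sub.empty:
            raise EmptyInputError(f"no cells with genotype {genotype!r}")
        prov = dict(self.provenance)
        prov["genotype_filter"] = genotype
        return CellTable(sub, provenance=prov, validate=False)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise EmptyInputError("cell table has no rows")
    df = df[COLUMNS].copy()

    for col in ("embryo_id", "genotype", "half", "cell_id"):
        df[col] = df[col].astype(str)

    bad_half = ~df["half"].isin(_HALVES)
    if bad_half.any():
        row = int(np.flatnonzero(bad_half.to_numpy())[0])
        raise ValidationError(
            f"row {row}: half must be one of {_HALVES}, got {df['half'].iloc[row]!r}"
        )

    for col in ("slice_index", "her1_count", "her7_count", "volume"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValidationError(f"row {row}: non-numeric value in {col!r}")
        df[col] = vals

    for col in ("slice_index", "her1_count", "her7_count"):
        vals = df[col].to_numpy()
        neg = vals < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise ValidationError(f"row {row}: negative value in {col!r}")
        # raw counts/indices must be whole numbers; volume-corrected tables
        # bypass validation, so fractional values here are data errors
        if not np.allclose(vals, np.round(vals)):
            row = int(np.flatnonzero(~np.isclose(vals, np.round(vals)))[0])
            raise ValidationError(f"row {row}: non-integer value in {col!r}")
        df[col] = df[col].astype(np.int64)

    nonpos = df["volume"].to_numpy() <= 0
    if nonpos.any():
        row = int(np.flatnonzero(nonpos)[0])
        raise ValidationError(f"row {row}: volume must be > 0")
    df["volume"] = df["volume"].astype(float)

    dup = df.duplicated(subset=["embryo_id", "half", "slice_index", "cell_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"row {row}: duplicate (embryo_id, half, slice_index, cell_id)"
        )
    return df


def read_cell_table(path, dialect: str = "csv") -> CellTable:
    """Read and validate a per-cell count table from delimited text."""
    path = Path(path)
    if dialect not in ("csv", "tsv"):
        raise ValueError("dialect must be 'csv' or 'tsv'")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="," if dialect == "csv" else "\t",
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if df.empty:
        raise EmptyInputError(f"{path} has a header but no rows")
    return CellTable(df, provenance={"path": str(path), "dialect": dialect})


def write_cell_table(table: CellTable, path, dialect: str = "csv") -> None:
    """Write a cell table as delimited text with the canonical header."""
    if len(table) == 0:
        raise EmptyInputError("refusing to write an empty cell table")
    sep = "," if dialect == "csv" else "\t"
    # repr round-trips float64 exactly (shortest representation)
    table.df[COLUMNS].to_csv(path, sep=sep, index=False,
                             float_format=lambda v: repr(float(v)))


def import_mapped_table(
    path,
    column_map: Mapping[str, str],
    genotype: str | None = None,
    dialect: str = "csv",
) -> CellTable:
    """Import a spreadsheet export with arbitrary column names.

    ``column_map`` maps canonical names (see :data:`COLUMNS`) to the source
    file's column names.  A constant ``genotype`` label may be supplied
    instead of a genotype column.  ``.xlsx`` sources are read via pandas'
    Excel reader; anything else as delimited text.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path, sep="," if dialect == "csv" else "\t")
    out = {}
    for canon in COLUMNS:
        if canon == "genotype" and genotype is not None:
            out[canon] = genotype
            continue
        src = column_map.get(canon)
        if src is None:
            raise SchemaError(f"column_map does not cover required column {canon!r}")
        if src not in raw.columns:
            raise SchemaError(f"source file has no column {src!r} (for {canon!r})")
        out[canon] = raw[src]
    return CellTable(pd.DataFrame(out), provenance={"path": str(path),
                                                    "column_map": dict(column_map)})


def _curve_to_dict(curve: BinnedCurve) -> dict:
    return {
        "genotype": curve.genotype,
        "volume_corrected": curve.volume_corrected,
        "n_bins": curve.n_bins,
        "bins": [
            {
                "bin_mean_her": float(curve.bin_mean_her[i]),
                "mean_correlated": float(curve.mean_correlated[i]),
                "mean_uncorrelated": float(curve.mean_uncorrelated[i]),
                "mean_total": float(curve.mean_total[i]),
                "se_correlated": float(curve.se_correlated[i]),
                "se_uncorrelated": float(curve.se_uncorrelated[i]),
                "n_slices": int(curve.n_slices[i]),
            }
            for i in range(curve.n_bins)
        ],
    }


def _curve_from_dict(d: dict) -> BinnedCurve:
    bins = d["bins"]

    def col(k):
        return np.array([b[k] for b in bins])

    return BinnedCurve(
        bin_mean_her=col("bin_mean_her"),
        mean_correlated=col("mean_correlated"),
        mean_uncorrelated=col("mean_uncorrelated"),
        mean_total=col("mean_total"),
        se_correlated=col("se_correlated"),
        se_uncorrelated=col("se_uncorrelated"),
        n_slices=col("n_slices").astype(int),
        n_bins=int(d["n_bins"]),
        volume_corrected=bool(d["volume_corrected"]),
        genotype=d["genotype"],
    )


def write_results(curves, comparison=None, path=None) -> None:
    """Serialise binned curves (and optionally an AUC comparison) as JSON."""
    payload = {"curves": [_curve_to_dict(c) for c in curves]}
    if comparison is not None:
        payload["comparison"] = comparison.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_results(path):
    """Inverse of :func:`write_results`.

    Returns ``(curves, comparison_dict_or_None)``; the comparison block is
    returned as a plain dict.
    """
    with open(path) as fh:
        payload = json.load(fh)
    curves = [_curve_from_dict(d) for d in payload["curves"]]
    return curves, payload.get("comparison")
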