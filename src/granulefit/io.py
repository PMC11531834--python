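"""Readers and writers for binned traces, sample sheets and output tables.

Interchange format for one instrument trace is delimited text (comma for
``.csv``, tab for ``.tsv``/``.tab``) with header columns

    bin_low_um, bin_high_um, value

plus inline per-row metadata columns (``sample_id``, ``genotype``, ``plant``,
``dpa``, ``weighting``, ``value_kind``; constant within a file).  The writer
emits a fixed column order, '.' decimal separator and LF line endings so that
write → read round trips are lossless.  Decimal-comma files are rejected
unless ``decimal=','`` is passed explicitly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import BinnedDistribution, ValueKind, Weighting
from .errors import ParseError

__all__ = [
    "SampleSheet",
    "read_trace",
    "write_trace",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_table",
]

_TRACE_COLUMNS = ("bin_low_um", "bin_high_um", "value")
_META_COLUMNS = ("sample_id", "genotype", "plant", "dpa", "weighting", "value_kind")

SHEET_REQUIRED = ("sample_id", "genotype", "plant", "aliquot_volume_mL",
                  "total_volume_mL", "trace_path")
SHEET_OPTIONAL = ("dpa", "grain_mass_mg", "counted_granules")


def _sep_for(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in (".tsv", ".tab") else ","


@dataclass(frozen=True)
class SampleSheet:
    """Validated table of measurements: one row per trace file."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", self.rows.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.rows)

    def by_plant(self):
        """Iterate ((genotype, plant, dpa), sub-table) groups."""
        cols = ["genotype", "plant"]
        if "dpa" in self.rows.columns and self.rows["dpa"].notna().any():
            cols.append("dpa")
        return self.rows.groupby(cols, dropna=False, sort=True)


def read_trace(path, *, decimal: str = ".") -> BinnedDistribution:
    """Read one binned trace file into a validated BinnedDistribution."""
    sep = _sep_for(path)
    try:
        df = pd.read_csv(path, sep=sep, decimal=decimal)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimiter/quoting
        raise ParseError(f"could not parse trace: {exc}", path=path) from exc
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", path=path)
    for col in _TRACE_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else None  # 1-based + header
            raise ParseError(f"non-numeric entry in column {col!r}",
                             path=path, row=row)
    low = df["bin_low_um"].to_numpy(float)
    high = df["bin_high_um"].to_numpy(float)
    values = df["value"].to_numpy(float)
    for i in range(len(df)):
        if not (0 < low[i] < high[i]):
            raise ParseError(
                f"bin [{low[i]}, {high[i]}] is not a positive increasing interval",
                path=path, row=i + 2)
        if i and not np.isclose(low[i], high[i - 1], rtol=1e-9):
            raise ParseError(
                f"bins not contiguous: previous high {high[i-1]} vs low {low[i]}",
                path=path, row=i + 2)
        if values[i] < 0:
            raise ParseError(f"negative value {values[i]}", path=path, row=i + 2)
    edges = np.append(low, high[-1])

    meta = {}
    for col in _META_COLUMNS:
        if col in df.columns and df[col].notna().any():
            uniq = df[col].dropna().unique()
            if len(uniq) != 1:
                raise ParseError(f"metadata column {col!r} is not constant",
                                 path=path)
            meta[col] = uniq[0]
    weighting = Weighting(meta.pop("weighting", "volume"))
    value_kind = ValueKind(meta.pop("value_kind", "percent"))
    try:
        return BinnedDistribution(edges, values, weighting, value_kind, meta=meta)
    except ValueError as exc:
        raise ParseError(f"invalid distribution: {exc}", path=path) from exc


def write_trace(dist: BinnedDistribution, path) -> None:
    """Write a trace in the canonical dialect (round-trips via read_trace)."""
    df = pd.DataFrame({
        "bin_low_um": dist.bin_edges[:-1],
        "bin_high_um": dist.bin_edges[1:],
        "value": dist.values,
    })
    df["weighting"] = dist.weighting.value
    df["value_kind"] = dist.value_kind.value
    for col in ("sample_id", "genotype", "plant", "dpa"):
        if col in dist.meta and dist.meta[col] is not None:
            df[col] = dist.meta[col]
    df.to_csv(path, sep=_sep_for(path), index=False,
              lineterminator="\n", float_format="%.12g")


def read_sample_sheet(path, *, genotype_levels: Optional[Sequence[str]] = None,
                      decimal: str = ".") -> SampleSheet:
    """Read and validate a sample sheet.

    ``genotype_levels``, when given, is the declared factor-level list;
    genotypes outside it are rejected.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path), decimal=decimal)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"could not parse sample sheet: {exc}", path=path) from exc
    missing = [c for c in SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", path=path)
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        row = int(dup.index[0]) + 2
        raise ParseError(f"duplicate sample_id {dup.iloc[0]!r}", path=path, row=row)
    empty = df["trace_path"].isna() | (df["trace_path"].astype(str).str.len() == 0)
    if empty.any():
        row = int(df.index[empty][0]) + 2
        raise ParseError("empty trace_path", path=path, row=row)
    if genotype_levels is not None:
        bad = ~df["genotype"].isin(list(genotype_levels))
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise ParseError(
                f"unknown genotype {df.loc[df.index[bad][0], 'genotype']!r} "
                f"(declared levels: {sorted(genotype_levels)})",
                path=path, row=row)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    cols = [c for c in (*SHEET_REQUIRED, *SHEET_OPTIONAL) if c in sheet.rows.columns]
    extra = [c for c in sheet.rows.columns if c not in cols]
    sheet.rows[cols + extra].to_csv(path, sep=_sep_for(path), index=False,
                                    lineterminator="\n")


def write_table(df: pd.DataFrame, path) -> None:
    """Write an output table (fits, phenotypes, comparisons) with a stable dialect."""
    df.to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n",
              float_format="%.10g")
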