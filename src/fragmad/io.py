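"""Text-format I/O: BED fragment tables, bin/profile TSVs, concentration CSVs.

All coordinates are 0-based half-open (BED convention). Only plain-text
formats are supported here; aligned-read (BAM) ingestion is deliberately
out of the core path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cnprofile import BinCounts, CopyNumberProfile
from .synthgen import BinSet

__all__ = [
    "read_fragments",
    "write_fragments",
    "read_bins",
    "write_bins",
    "write_profile",
    "read_profile",
    "read_concentrations",
    "write_concentrations",
]

_FRAGMENT_COLUMNS = ["chrom", "start", "end", "origin"]


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a BED3(+) fragment table (tab-separated, no header).

    Columns: chromosome, start, end, optional origin label. Malformed lines
    are reported with their 1-based line number; ``end <= start`` is a
    parse error (fragments must have length >= 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, skip_blank_lines=False
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_FRAGMENT_COLUMNS[:3])
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected at least 3 tab-separated columns")
    df = df.iloc[:, :4]
    df.columns = _FRAGMENT_COLUMNS[: df.shape[1]]

    for col in ("start", "end"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(f"{path}:{line}: non-integer {col!r} field")
        df[col] = converted.astype(np.int64)
    invalid = df["end"] <= df["start"]
    if invalid.any():
        line = int(np.flatnonzero(invalid)[0]) + 1
        raise ValueError(f"{path}:{line}: end <= start")
    return df.reset_index(drop=True)


def write_fragments(fragments: pd.DataFrame, path: str | Path) -> None:
    """Write a fragment table as headerless tab-separated BED3(+)."""
    cols = [c for c in _FRAGMENT_COLUMNS if c in fragments.columns]
    fragments.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def write_bins(bins: BinSet, path: str | Path) -> None:
    """Write a bin annotation table (TSV with header)."""
    df = bins.to_frame()
    df["gc"] = df["gc"].map(lambda v: f"{v:.9g}")
    df.to_csv(path, sep="\t", index=False)


def read_bins(path: str | Path) -> BinSet:
    """Read a bin annotation table written by :func:`write_bins`."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gc", "usable"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: bin table lacks columns {sorted(missing)}")
    return BinSet(
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        gc=df["gc"].to_numpy(dtype=float),
        usable=df["usable"].astype(bool).to_numpy(),
    )


def write_profile(
    path: str | Path,
    bins: BinSet,
    counts: BinCounts | None = None,
    profile: CopyNumberProfile | None = None,
) -> None:
    """Serialize bins + counts + log2 profile as one TSV.

    Columns: chrom, start, end, gc, raw, corrected, log2ratio, usable.
    Fields not yet computed (and masked log2 ratios) are written as ``NA``.
    Row order follows the bin order, so output is deterministic.
    """
    n = bins.n_bins
    df = bins.to_frame()[["chrom", "start", "end", "gc"]]
    df["raw"] = counts.raw if counts is not None else np.full(n, np.nan)
    if counts is not None and counts.corrected is not None:
        df["corrected"] = counts.corrected
    else:
        df["corrected"] = np.full(n, np.nan)
    if profile is not None:
        df["log2ratio"] = profile.log2
        df["usable"] = profile.usable
    else:
        df["log2ratio"] = np.full(n, np.nan)
        df["usable"] = (
            counts.usable if counts is not None else bins.usable
        )
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.9g")


def read_profile(path: str | Path) -> pd.DataFrame:
    """Read a profile TSV back as a DataFrame (``NA`` -> NaN)."""
    df = pd.read_csv(path, sep="\t", na_values="NA")
    required = {"chrom", "start", "end", "gc", "raw", "corrected", "log2ratio", "usable"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: profile table lacks columns {sorted(missing)}")
    return df


def read_concentrations(path: str | Path) -> pd.DataFrame:
    """Read a concentration series CSV (patient,histology,timepoint,ng_per_ml)."""
    df = pd.read_csv(path)
    required = {"patient", "histology", "timepoint", "ng_per_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: concentration table lacks columns {sorted(missing)}")
    df["ng_per_ml"] = df["ng_per_ml"].astype(float)
    return df


def write_concentrations(series: pd.DataFrame, path: str | Path) -> None:
    """Write a concentration series CSV with the canonical header."""
    series.to_csv(
        path,
        index=False,
        columns=["patient", "histology", "timepoint", "ng_per_ml"],
        float_format="%.9g",
    )
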