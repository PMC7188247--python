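"""In-silico size selection and the tMAD ctDNA detection statistic.

Tumor-derived cfDNA fragments run shorter than the mononucleosomal ~167 bp
of healthy-cell cfDNA, so restricting a fragment table to a 90-150 bp
window enriches the tumor fraction without any wet-lab step. Genome-wide
SCNA burden is then summarized by tMAD — the trimmed median absolute
deviation of bin log2 ratios from copy-number neutrality (zero) — and a
sample is flagged ctDNA-positive when tMAD strictly exceeds the detection
threshold (0.015 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnprofile import (
    BinCounts,
    CopyNumberProfile,
    SCNACall,
    call_scnas,
    count_fragments,
    gc_correct,
    to_log2_profile,
)
from .synthgen import BinSet

__all__ = [
    "SizeSelectionConfig",
    "TMADResult",
    "QCResult",
    "ArmResult",
    "PipelineComparison",
    "size_select",
    "tmad",
    "detect_ctdna",
    "qc_depth",
    "compare_pipelines",
]

#: tMAD detection threshold: a sample is called ctDNA-positive when its
#: tMAD is strictly greater than this value.
DEFAULT_TMAD_THRESHOLD = 0.015

#: Minimum fragments per sample for the depth QC (a warning, not a stop).
DEFAULT_MIN_FRAGMENTS = 5_000_000


@dataclass(frozen=True)
class SizeSelectionConfig:
    """Inclusive fragment-length window in bp (default 90-150)."""

    lower: int = 90
    upper: int = 150

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.upper):
            raise ValueError("need 0 < lower <= upper")


@dataclass(frozen=True)
class TMADResult:
    """tMAD of a log2 profile with its trim fraction and detection call."""

    value: float
    q: float
    n_bins: int
    threshold: float
    detected: bool


@dataclass(frozen=True)
class QCResult:
    """Read-depth QC: pass/fail against a minimum fragment count."""

    n_fragments: int
    min_fragments: int
    passed: bool


def size_select(
    fragments: pd.DataFrame, cfg: SizeSelectionConfig | None = None
) -> pd.DataFrame:
    """Retain exactly the fragments with lower <= length <= upper.

    Length is ``end - start``. Order is preserved; retained/dropped counts
    are attached as ``attrs['n_retained']`` / ``attrs['n_dropped']``.
    Idempotent: applying the same window twice changes nothing.
    """
    cfg = cfg or SizeSelectionConfig()
    lengths = np.asarray(fragments["end"]) - np.asarray(fragments["start"])
    keep = (lengths >= cfg.lower) & (lengths <= cfg.upper)
    out = fragments.loc[keep].reset_index(drop=True)
    out.attrs["n_retained"] = int(keep.sum())
    out.attrs["n_dropped"] = int(len(fragments) - keep.sum())
    return out


def tmad(
    profile: CopyNumberProfile,
    q: float = 0.05,
    threshold: float = DEFAULT_TMAD_THRESHOLD,
    min_bins: int = 10,
) -> TMADResult:
    """Trimmed median absolute deviation from copy-number neutrality.

    Deviations are ``|r_i - 0|`` over usable bins; the ``ceil(q * n)``
    largest are discarded (one-sided trim of the most aberrant bins) and
    the median of the rest is the tMAD. No MAD scale constant is applied:
    the detection threshold lives on this raw scale. ``q = 0`` is the plain
    median absolute deviation from zero.
    """
    if not (0.0 <= q < 0.5):
        raise ValueError("trim fraction q must lie in [0, 0.5)")
    r = profile.values
    r = r[np.isfinite(r)]
    n = len(r)
    if n < min_bins:
        raise ValueError(f"tMAD needs at least {min_bins} usable bins (got {n})")
    d = np.sort(np.abs(r))
    k = math.ceil(q * n)
    retained = d[: n - k] if k else d
    value = float(np.median(retained))
    return TMADResult(
        value=value,
        q=q,
        n_bins=n,
        threshold=threshold,
        detected=value > threshold,
    )


def detect_ctdna(
    result: TMADResult | float, threshold: float = DEFAULT_TMAD_THRESHOLD
) -> bool:
    """ctDNA detection rule: tMAD strictly greater than the threshold."""
    value = result.value if isinstance(result, TMADResult) else float(result)
    if value < 0:
        raise ValueError("tMAD must be >= 0")
    return value > threshold


def qc_depth(
    fragments: pd.DataFrame, min_fragments: int = DEFAULT_MIN_FRAGMENTS
) -> QCResult:
    """Flag samples below the minimum fragment count.

    Failing the depth QC does not stop processing — under-sequenced samples
    remain assessable — but the flag is carried into every downstream
    report.
    """
    n = len(fragments)
    return QCResult(n_fragments=n, min_fragments=min_fragments, passed=n >= min_fragments)


@dataclass
class ArmResult:
    """One processing arm (all fragments, or size-selected)."""

    n_fragments: int
    profile: CopyNumberProfile
    tmad: TMADResult
    calls: list[SCNACall]


@dataclass
class PipelineComparison:
    """Side-by-side report of the unselected vs size-selected pipeline."""

    qc: QCResult
    unselected: ArmResult
    selected: ArmResult
    size_cfg: SizeSelectionConfig

    def to_dict(self) -> dict:
        def arm(a: ArmResult) -> dict:
            return {
                "n_fragments": a.n_fragments,
                "tmad": a.tmad.value,
                "trim_q": a.tmad.q,
                "threshold": a.tmad.threshold,
                "detected": a.tmad.detected,
                "n_usable_bins": a.tmad.n_bins,
                "calls": [
                    {
                        "start_bin": c.start_bin,
                        "end_bin": c.end_bin,
                        "direction": c.direction,
                        "mean_log2": round(c.mean_log2, 9),
                    }
                    for c in a.calls
                ],
            }

        return {
            "qc": {
                "n_fragments": self.qc.n_fragments,
                "min_fragments": self.qc.min_fragments,
                "passed": self.qc.passed,
            },
            "size_selection": {"lower": self.size_cfg.lower, "upper": self.size_cfg.upper},
            "unselected": arm(self.unselected),
            "selected": arm(self.selected),
        }


def _run_arm(
    fragments: pd.DataFrame,
    bins: BinSet,
    q: float,
    threshold: float,
    gain_thresh: float,
    loss_thresh: float,
    min_bins_call: int,
    gc_frac: float,
    gc_correction: bool,
) -> ArmResult:
    counts = count_fragments(fragments, bins)
    if gc_correction:
        counts = gc_correct(counts, bins, frac=gc_frac)
    profile = to_log2_profile(counts)
    t = tmad(profile, q=q, threshold=threshold)
    calls = call_scnas(
        profile, gain_thresh=gain_thresh, loss_thresh=loss_thresh, min_bins=min_bins_call
    )
    return ArmResult(
        n_fragments=len(fragments), profile=profile, tmad=t, calls=calls
    )


def compare_pipelines(
    fragments: pd.DataFrame,
    bins: BinSet,
    size_cfg: SizeSelectionConfig | None = None,
    q: float = 0.05,
    threshold: float = DEFAULT_TMAD_THRESHOLD,
    gain_thresh: float = 0.15,
    loss_thresh: float = -0.15,
    min_bins_call: int = 10,
    gc_frac: float = 0.5,
    gc_correction: bool = True,
    min_fragments: int = DEFAULT_MIN_FRAGMENTS,
) -> PipelineComparison:
    """Run the full profiling pipeline with and without size selection.

    Both arms share the identical count -> GC-correct -> log2-profile ->
    tMAD/SCNA-call path; the selected arm first restricts fragments to the
    size window. Deterministic: identical inputs give identical reports.
    """
    cfg = size_cfg or SizeSelectionConfig()
    qc = qc_depth(fragments, min_fragments=min_fragments)
    args = (q, threshold, gain_thresh, loss_thresh, min_bins_call, gc_frac, gc_correction)
    unselected = _run_arm(fragments, bins, *args)
    selected = _run_arm(size_select(fragments, cfg), bins, *args)
    return PipelineComparison(qc=qc, unselected=unselected, selected=selected, size_cfg=cfg)
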