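"""End-to-end driver: configuration, run_all, and the run report.

A :class:`RunConfig` captures every parameter of a run (simulation or
ingestion, profiling, size selection, tMAD, SCNA calling, dynamics) and
round-trips losslessly through YAML. :func:`run_all` executes
simulate/ingest -> count -> GC-correct -> log2 profile -> {tMAD, SCNA
calls} with and without size selection, plus the concentration-dynamics
summaries when a concentration table is supplied, and returns a single
JSON-serializable report. All randomness flows from ``config.seed``; a
fixed seed gives a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dynamics import (
    DEFAULT_BASELINE_TIMEPOINTS,
    PART1_GROUPING,
    bland_altman,
    change_from_baseline,
    rank_sum_exact,
    summarize_baseline,
)
from .fragmentomics import (
    SizeSelectionConfig,
    compare_pipelines,
)
from .io import read_bins, read_concentrations, read_fragments
from .synthgen import (
    gaussian_gc_bias,
    make_bins,
    make_truth,
    neutral_truth,
    simulate_fragments,
)

__all__ = ["RunConfig", "RunReport", "run_all"]

logger = logging.getLogger("fragmad")


@dataclass
class RunConfig:
    """Every knob of one pipeline run, with its documented default."""

    seed: int = 0
    # --- inputs (None => simulate) ---
    fragments_path: str | None = None
    bins_path: str | None = None
    concentrations_path: str | None = None
    # --- simulation ---
    n_bins: int = 100
    bin_size: int = 1_000_000
    gc_low: float = 0.35
    gc_high: float = 0.55
    n_fragments: int = 5_000_000
    tumor_fraction: float = 0.0
    #: gained/lost segments as [lo_bin, hi_bin, copy_number]; None = neutral
    segments: list[list[float]] | None = None
    #: strength k of the multiplicative GC bias exp(-k (gc-0.45)^2); 0 = none
    gc_bias_k: float = 20.0
    # --- size selection ---
    size_lower: int = 90
    size_upper: int = 150
    # --- tMAD / detection ---
    trim_q: float = 0.05
    tmad_threshold: float = 0.015
    # --- SCNA calling ---
    gain_thresh: float = 0.15
    loss_thresh: float = -0.15
    min_bins_call: int = 10
    # --- GC correction ---
    gc_frac: float = 0.5
    gc_correction: bool = True
    # --- QC ---
    min_fragments_qc: int = 5_000_000

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Aggregated, JSON-serializable result of one run."""

    report: dict

    def to_json(self) -> str:
        return json.dumps(self.report, sort_keys=True, indent=2)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _dynamics_report(series, config: RunConfig) -> dict:
    out: dict = {}
    base = summarize_baseline(series)
    out["baseline"] = {
        "median": base.median,
        "min": base.minimum,
        "max": base.maximum,
        "n": base.n,
        "group_means": base.group_means,
        "group_n": base.group_n,
    }
    timepoints = set(series["timepoint"])
    if timepoints <= set(PART1_GROUPING):
        ba = bland_altman(series, PART1_GROUPING)
        out["bland_altman"] = {
            "mean_diff": ba.mean_diff,
            "sd_diff": ba.sd_diff,
            "lower": ba.lower,
            "upper": ba.upper,
            "n": ba.n,
        }
    deltas = {}
    for tp in sorted(timepoints - set(DEFAULT_BASELINE_TIMEPOINTS)):
        ds = change_from_baseline(series, tp)
        entry: dict = {
            "by_histology": ds.by_histology,
            "excluded": ds.excluded,
            "n_included": ds.n_included,
        }
        hists = sorted(ds.by_histology)
        if len(hists) == 2:
            groups = {h: [] for h in hists}
            hist_of = dict(zip(series["patient"], series["histology"]))
            for p, d in ds.deltas.items():
                groups[hist_of[p]].append(d)
            if all(groups.values()):
                entry["rank_sum_p"] = rank_sum_exact(groups[hists[0]], groups[hists[1]])
        deltas[tp] = entry
    if deltas:
        out["change_from_baseline"] = deltas
    return out


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline described by ``config``.

    Startup validation happens before any compute: configured input paths
    must exist. Stage failures are re-raised with the stage name attached.
    """
    for label, p in (
        ("fragments_path", config.fragments_path),
        ("bins_path", config.bins_path),
        ("concentrations_path", config.concentrations_path),
    ):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{label}: no such file: {p}")

    stage = "setup"
    try:
        if config.fragments_path is not None:
            stage = "ingest"
            if config.bins_path is None:
                raise ValueError("fragments_path requires bins_path")
            fragments = read_fragments(config.fragments_path)
            bins = read_bins(config.bins_path)
            simulated = False
        else:
            stage = "simulate"
            bins = (
                read_bins(config.bins_path)
                if config.bins_path is not None
                else make_bins(
                    config.n_bins,
                    config.bin_size,
                    gc_range=(config.gc_low, config.gc_high),
                    seed=config.seed,
                )
            )
            if config.segments is None:
                truth = neutral_truth(bins, tf=config.tumor_fraction)
            else:
                truth = make_truth(
                    bins,
                    [((int(lo), int(hi)), float(c)) for lo, hi, c in config.segments],
                    tf=config.tumor_fraction,
                )
            bias = gaussian_gc_bias(config.gc_bias_k) if config.gc_bias_k > 0 else None
            fragments = simulate_fragments(
                truth,
                bins,
                config.n_fragments,
                gc_bias=bias,
                seed=config.seed,
            )
            simulated = True
        logger.info("stage=%s fragments=%d bins=%d", stage, len(fragments), bins.n_bins)

        stage = "profile"
        comparison = compare_pipelines(
            fragments.drop(columns=["origin"], errors="ignore"),
            bins,
            size_cfg=SizeSelectionConfig(config.size_lower, config.size_upper),
            q=config.trim_q,
            threshold=config.tmad_threshold,
            gain_thresh=config.gain_thresh,
            loss_thresh=config.loss_thresh,
            min_bins_call=config.min_bins_call,
            gc_frac=config.gc_frac,
            gc_correction=config.gc_correction,
            min_fragments=config.min_fragments_qc,
        )
        logger.info(
            "stage=profile tmad_unselected=%.6f tmad_selected=%.6f",
            comparison.unselected.tmad.value,
            comparison.selected.tmad.value,
        )

        report: dict = {
            "provenance": {
                "version": __version__,
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "config": config.to_dict(),
                "simulated_fragments": simulated,
            },
            "sample": comparison.to_dict(),
        }

        if config.concentrations_path is not None:
            stage = "dynamics"
            series = read_concentrations(config.concentrations_path)
            report["dynamics"] = _dynamics_report(series, config)
        return RunReport(report=report)
    except Exception as exc:  # annotate with the failing stage
        raise type(exc)(f"[stage {stage}] {exc}") from exc
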