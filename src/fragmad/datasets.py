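"""Bundled example data: the ten-patient NSCLC chemo-radiotherapy cohort.

Baseline plasma cfDNA concentrations (ng/ml) for ten locally advanced
NSCLC patients treated with concurrent chemo-radiotherapy in a two-part
blood-sampling design: patients 1-4 (part 1) sampled densely around single
chemo/radiotherapy events, patients 5-10 (part 2) sampled across the whole
treatment course. For part-1 patients the stored value is the mean of the
baseline test and retest draws, so every patient carries exactly one
baseline record. Histology is adenocarcinoma (AC) or squamous cell
carcinoma (SCC).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "cohort_baseline",
    "baseline_series",
    "PART1_PATIENTS",
    "PART2_PATIENTS",
]

_COHORT = [
    # (patient, histology, study part, baseline cfDNA ng/ml plasma)
    ("p01", "AC", 1, 5.85),
    ("p02", "SCC", 1, 17.78),
    ("p03", "SCC", 1, 1.50),
    ("p04", "SCC", 1, 4.13),
    ("p05", "AC", 2, 3.60),
    ("p06", "AC", 2, 2.79),
    ("p07", "SCC", 2, 7.85),
    ("p08", "SCC", 2, 8.27),
    ("p09", "AC", 2, 2.52),
    ("p10", "SCC", 2, 1.47),
]

PART1_PATIENTS = tuple(p for p, _, part, _ in _COHORT if part == 1)
PART2_PATIENTS = tuple(p for p, _, part, _ in _COHORT if part == 2)


def cohort_baseline() -> pd.DataFrame:
    """Cohort table: patient, histology, part, baseline_ng_per_ml."""
    return pd.DataFrame(
        _COHORT, columns=["patient", "histology", "part", "baseline_ng_per_ml"]
    )


def baseline_series() -> pd.DataFrame:
    """The cohort as a long-format concentration series (timepoint 'baseline').

    Shaped for :mod:`fragmad.dynamics` (columns patient, histology,
    timepoint, ng_per_ml).
    """
    df = cohort_baseline()
    return pd.DataFrame(
        {
            "patient": df["patient"],
            "histology": df["histology"],
            "timepoint": "baseline",
            "ng_per_ml": df["baseline_ng_per_ml"],
        }
    )
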