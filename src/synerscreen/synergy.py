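"""Fractional-product (Webb/Bliss) synergy statistic R and its classification.

The fractional product method scores a drug pair on the surviving-fraction
scale: under Bliss independence the expected combined survival is the product
of the single-agent survivals, and

    R = s_combo / (s_a * s_b)

so R < 1 means the observed kill exceeds the independence expectation
(synergy), R = 1 additivity, R > 1 antagonism.  The hit-calling thresholds
used throughout the screen are R < 0.4 (strong synergy) and 0.4 <= R < 0.7
(synergy).  The same statistic applies to apoptosis data (on the non-apoptotic
fraction) and to in-vivo data (on fractional tumor volumes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_io import add_tumor_volumes, TUMOR_GROUPS

LABELS = ("strong_synergy", "synergy", "non_synergy", "antagonism")


@dataclass(frozen=True)
class SynergyThresholds:
    """Cut points and gates of the hit-calling cascade.

    strong_cut / synergy_cut / antagonism_cut partition the R axis;
    combined_kill_gate and cytotoxic_alone_gate are the primary-screen
    fractional-kill gates; expected_survival_floor excludes dose pairs whose
    Bliss-expected survival is so low that R is a ratio of assay noise.
    """

    strong_cut: float = 0.4
    synergy_cut: float = 0.7
    antagonism_cut: float = 1.0
    combined_kill_gate: float = 0.8
    cytotoxic_alone_gate: float = 0.9
    expected_survival_floor: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.strong_cut < self.synergy_cut <= self.antagonism_cut):
            raise ValueError("need 0 < strong_cut < synergy_cut <= antagonism_cut")


@dataclass(frozen=True)
class SynergyResult:
    """R for one dose pair (or one compound), with the fractions that produced it."""

    R: float
    s_combo: float
    s_a: float
    s_b: float
    label: str | None
    dose_a: float | None = None
    dose_b: float | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.R)


def bliss_expected_survival(s_a: float, s_b: float):
    """Bliss-independence expected combined survival: the fractional product."""
    return np.multiply(s_a, s_b)


def classify_R(R: float, thresholds: SynergyThresholds = SynergyThresholds()) -> str:
    """Label an R value: strong_synergy / synergy / non_synergy / antagonism.

    Boundaries: strong synergy is strict (R < strong_cut); synergy is the
    half-open band [strong_cut, synergy_cut); antagonism requires
    R > antagonism_cut.
    """
    if not np.isfinite(R) or R < 0:
        raise ValueError(f"R must be finite and nonnegative, got {R}")
    if R < thresholds.strong_cut:
        return "strong_synergy"
    if R < thresholds.synergy_cut:
        return "synergy"
    if R <= thresholds.antagonism_cut:
        return "non_synergy"
    return "antagonism"


def fractional_product_R(
    s_combo: float,
    s_a: float,
    s_b: float,
    thresholds: SynergyThresholds = SynergyThresholds(),
    dose_a: float | None = None,
    dose_b: float | None = None,
) -> SynergyResult:
    """Compute R = s_combo / (s_a * s_b) and classify it.

    If the Bliss-expected survival is zero the ratio is undefined; the result
    carries R = nan and no label, and callers exclude it from summaries.
    """
    for name, s in (("s_combo", s_combo), ("s_a", s_a), ("s_b", s_b)):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"{name} must be a fraction in [0, 1], got {s}")
    expected = s_a * s_b
    if expected == 0.0:
        return SynergyResult(float("nan"), s_combo, s_a, s_b, None, dose_a, dose_b)
    R = s_combo / expected
    return SynergyResult(R, s_combo, s_a, s_b, classify_R(R, thresholds), dose_a, dose_b)


def apoptosis_to_survival(apoptotic_fraction: float) -> float:
    """Complement of the apoptotic fraction, for R on the surviving scale."""
    if not 0.0 <= apoptotic_fraction <= 1.0:
        raise ValueError("apoptotic fraction must lie in [0, 1]")
    return 1.0 - apoptotic_fraction


def tumor_growth_R(
    measurements: pd.DataFrame,
    day: int,
    thresholds: SynergyThresholds = SynergyThresholds(),
) -> SynergyResult:
    """Fractional-product R on mean fractional tumor volumes at one day.

    Each treated group's mean volume is divided by the control-group mean to
    give a fractional volume, and R = fv_combination / (fv_drug_a * fv_drug_b).
    All four groups (control, drug_a, drug_b, combination) must be present at
    the requested day.
    """
    df = measurements
    if "volume_mm3" not in df.columns:
        df = add_tumor_volumes(df)
    at_day = df[df["day"] == day]
    means = at_day.groupby("group")["volume_mm3"].mean()
    missing = [g for g in TUMOR_GROUPS if g not in means.index]
    if missing:
        raise ValueError(f"missing groups {missing} at day {day}")
    fv = means / means["control"]
    # fractional volumes may exceed 1 (a treated group can outgrow control);
    # bypass the [0,1] fraction check used for viability data
    expected = fv["drug_a"] * fv["drug_b"]
    R = fv["combination"] / expected
    return SynergyResult(
        R, fv["combination"], fv["drug_a"], fv["drug_b"], classify_R(R, thresholds)
    )


def results_to_frame(results) -> pd.DataFrame:
    """Serialize SynergyResults to a flat table (doses in nM)."""
    rows = [
        {
            "dose_a_nM": r.dose_a,
            "dose_b_nM": r.dose_b,
            "R": r.R,
            "s_combo": r.s_combo,
            "s_a": r.s_a,
            "s_b": r.s_b,
            "label": r.label,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
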