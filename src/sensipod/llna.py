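"""LLNA EC3 derivation, study screening and reference-value aggregation.

The murine local lymph node assay (LLNA) measures lymphocyte proliferation in
the auricular nodes after topical application; the stimulation index (SI) is
proliferation relative to vehicle control and SI = 3 is the threshold
positive response. EC3 — the concentration (% w/v) estimated to produce
SI = 3 — is the in vivo potency metric and point of departure.

This module

* interpolates (or, when SI = 3 is not bracketed, extrapolates) EC3 from a
  single study's concentration/SI series;
* screens extrapolated values with the Ryan acceptability criteria (lowest
  measured SI < 5; extrapolated EC3 within 10-fold of the closest tested
  concentration; slope ratio <= 2 and non-negative);
* screens studies against the reference-data quality checklist (topical
  application to both ears, in vivo radiolabel, no SLS enhancement, ...);
* aggregates multiple studies into a representative reference EC3 under two
  approaches: Approach 1 selects the most potent acceptable study in a
  preferred solvent (acetone or 4:1 acetone:olive oil); Approach 2 averages
  all acceptable EC3 values with a t-based 95% CI, censored below at zero;
* assigns GHS potency subcategories (1A: EC3 <= 2%; 1B: EC3 > 2%; NC:
  negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dose_response import DoseResponseSeries
from .errors import InvalidInputError, NoReferenceError

SI_THRESHOLD = 3.0

#: Quality-checklist attributes a reference study must satisfy.
CHECKLIST_ATTRIBUTES = (
    "topical_both_ears",
    "draining_node_proliferation",
    "induction_phase",
    "vehicle_control",
    "concentration_si_available",
    "in_vivo_radiolabel",
    "no_sls_enhancement",
    "application_3_4_days",
)

#: Vehicles eligible for Approach 1 selection.
PREFERRED_VEHICLES = ("acetone", "acetone:olive oil 4:1")


@dataclass(frozen=True)
class LLNAStudy:
    chemical: str
    series: DoseResponseSeries
    vehicle: str = "acetone"
    acceptability_flags: dict = field(default_factory=dict)
    source: str = ""


@dataclass(frozen=True)
class EC3Estimate:
    """EC3 from one study. `value` is None for a negative call."""

    value: Optional[float]
    method: str  # "interpolated" | "extrapolated" | "negative"
    rejection_reasons: tuple = ()

    @property
    def accepted(self) -> bool:
        return len(self.rejection_reasons) == 0

    @property
    def negative(self) -> bool:
        return self.method == "negative"


@dataclass(frozen=True)
class ReferenceEC3:
    approach: str  # "A1" | "A2"
    mean: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_studies: int
    ghs_class: str


def ec3_from_study(series: DoseResponseSeries,
                   threshold: float = SI_THRESHOLD) -> EC3Estimate:
    """EC3 by linear interpolation in arithmetic concentration.

    The lowest bracketing pair below/above SI = 3 is used; an exact hit
    returns the tested concentration. When all SI fall short of 3 but the top
    of the curve still rises, EC3 is extrapolated from the line through the
    two highest concentrations (and must then pass the Ryan screen); when the
    lowest tested concentration already exceeds SI = 3 the extrapolation runs
    downward from the two lowest points. A flat-or-falling sub-threshold
    curve is a negative call.
    """
    if len(series) < 2:
        return EC3Estimate(None, "negative", ("no_data",))
    conc = np.asarray(series.concentrations, dtype=float)
    si = np.asarray(series.responses, dtype=float)

    for i in range(len(conc)):
        if si[i] == threshold:
            return EC3Estimate(float(conc[i]), "interpolated")
        if i + 1 < len(conc) and si[i] < threshold < si[i + 1]:
            t = (threshold - si[i]) / (si[i + 1] - si[i])
            return EC3Estimate(float(conc[i] + t * (conc[i + 1] - conc[i])),
                               "interpolated")

    if si[0] > threshold:
        # whole curve above threshold: extrapolate downward from the two lowest
        if si[1] == si[0]:
            return EC3Estimate(None, "negative", ("no_data",))
        t = (threshold - si[0]) / (si[1] - si[0])
        value = conc[0] + t * (conc[1] - conc[0])
        if value <= 0:
            value = float(conc[0] / 10.0)  # degenerate slope; screened out by 10x rule
        return EC3Estimate(float(value), "extrapolated")

    # all SI < threshold: upward extrapolation only if the top segment rises
    if si[-1] > si[-2]:
        t = (threshold - si[-2]) / (si[-1] - si[-2])
        return EC3Estimate(float(conc[-2] + t * (conc[-1] - conc[-2])),
                           "extrapolated")
    return EC3Estimate(None, "negative")


def ryan_screen(estimate: EC3Estimate, series: DoseResponseSeries,
                max_fold: float = 10.0) -> EC3Estimate:
    """Apply the acceptability criteria for extrapolated EC3 values.

    Interpolated and negative estimates pass through unchanged. An
    extrapolated estimate accrues a rejection reason per failed criterion:

    * ``lowest_si_ge_5`` — the lowest measured SI was not < 5;
    * ``extrapolation_gt_10x`` — EC3 not within 10-fold of the closest tested
      concentration (the highest tested for upward extrapolation, the lowest
      for downward);
    * ``slope_ratio_fail`` — the ratio of the outer to the inner slope over
      the three tested concentrations nearest the extrapolation was > 2 or
      negative, or could not be computed (< 3 concentrations).
    """
    if estimate.method != "extrapolated" or estimate.value is None:
        return estimate
    conc = np.asarray(series.concentrations, dtype=float)
    si = np.asarray(series.responses, dtype=float)
    reasons = list(estimate.rejection_reasons)

    if si.min() >= 5.0:
        reasons.append("lowest_si_ge_5")

    downward = estimate.value < conc[0]
    closest = conc[0] if downward else conc[-1]
    if downward:
        if estimate.value < closest / max_fold:
            reasons.append("extrapolation_gt_10x")
    elif estimate.value >= closest * max_fold:
        reasons.append("extrapolation_gt_10x")

    if len(conc) < 3:
        reasons.append("slope_ratio_fail")
    else:
        if downward:
            c3, s3 = conc[:3], si[:3]
            outer = (s3[1] - s3[0]) / (c3[1] - c3[0])
            inner = (s3[2] - s3[1]) / (c3[2] - c3[1])
        else:
            c3, s3 = conc[-3:], si[-3:]
            outer = (s3[2] - s3[1]) / (c3[2] - c3[1])
            inner = (s3[1] - s3[0]) / (c3[1] - c3[0])
        if inner == 0:
            reasons.append("slope_ratio_fail")
        else:
            ratio = outer / inner
            if ratio > 2.0 or ratio < 0.0:
                reasons.append("slope_ratio_fail")

    return replace(estimate, rejection_reasons=tuple(reasons))


def checklist_screen(study: LLNAStudy) -> tuple[bool, list]:
    """Check the study against the reference-data quality checklist.

    Returns (accepted, reasons); a missing flag counts as a failure.
    """
    reasons = [attr for attr in CHECKLIST_ATTRIBUTES
               if not study.acceptability_flags.get(attr, False)]
    return len(reasons) == 0, reasons


def screen_study(study: LLNAStudy, estimate: EC3Estimate) -> EC3Estimate:
    """Full screen: quality checklist plus the Ryan criteria."""
    ok, _ = checklist_screen(study)
    estimate = ryan_screen(estimate, study.series)
    if not ok:
        estimate = replace(estimate,
                           rejection_reasons=estimate.rejection_reasons + ("checklist_fail",))
    return estimate


def ghs_classify(ec3: Optional[float]) -> str:
    """GHS skin-sensitizer subcategory from EC3 (%): 1A for EC3 <= 2, 1B above,
    NC for a negative call (``None``)."""
    if ec3 is None:
        return "NC"
    if ec3 <= 0:
        raise InvalidInputError("numeric EC3 must be positive")
    return "1A" if ec3 <= 2.0 else "1B"


def approach1_select(studies: Sequence[tuple[LLNAStudy, EC3Estimate]],
                     preferred_vehicles: Sequence[str] = PREFERRED_VEHICLES,
                     tie_ratio: float = 1.25) -> ReferenceEC3:
    """Approach 1: the most potent acceptable study in a preferred vehicle.

    Eligible studies use one of `preferred_vehicles` and carry an accepted,
    positive EC3. The lowest EC3 wins; studies within `tie_ratio`-fold of it
    are treated as a tied set and reported as a range (as when two
    near-identical contemporaneous tests exist).
    """
    preferred = {v.strip().lower() for v in preferred_vehicles}
    eligible = [(s, e) for s, e in studies
                if s.vehicle.strip().lower() in preferred
                and e.accepted and e.value is not None]
    if not eligible:
        raise NoReferenceError("no acceptable study in a preferred vehicle")
    values = sorted(e.value for _, e in eligible)
    lowest = values[0]
    tied = [v for v in values if v <= lowest * tie_ratio]
    if len(tied) == 1:
        mean = lowest
        ci_low = ci_high = None
    else:
        mean = 0.5 * (min(tied) + max(tied))
        ci_low, ci_high = min(tied), max(tied)  # a range, not a CI
    return ReferenceEC3("A1", float(mean), ci_low, ci_high, len(tied),
                        ghs_classify(mean))


def approach2_aggregate(ec3_values: Sequence[float],
                        quantile: str = "t") -> ReferenceEC3:
    """Approach 2: mean of all acceptable EC3 values with a 95% CI.

    CI = mean +/- q(0.975) * sd / sqrt(n) with the Student-t quantile on
    n - 1 df (``quantile="normal"`` substitutes 1.96); the lower bound is
    censored at zero. A single study yields no CI. Negative studies
    contribute no EC3 and must be excluded by the caller.
    """
    values = np.asarray([v for v in ec3_values], dtype=float)
    if values.size == 0:
        raise NoReferenceError("no EC3 values to aggregate")
    if (values <= 0).any():
        raise InvalidInputError("EC3 values must be positive")
    mean = float(values.mean())
    if values.size == 1:
        ci_low = ci_high = None
    else:
        sd = float(values.std(ddof=1))
        if quantile == "t":
            q = float(stats.t.ppf(0.975, values.size - 1))
        elif quantile == "normal":
            q = float(stats.norm.ppf(0.975))
        else:
            raise InvalidInputError(f"unknown quantile rule {quantile!r}")
        half = q * sd / math.sqrt(values.size)
        ci_low = max(0.0, mean - half)
        ci_high = mean + half
    return ReferenceEC3("A2", mean, ci_low, ci_high, int(values.size),
                        ghs_classify(mean))
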