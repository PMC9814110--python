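"""h-CLAT endpoint derivation (THP-1 dendritic-cell activation test).

The human cell line activation test measures up-regulation of the
costimulatory/adhesion surface markers CD86 and CD54 on THP-1 cells by flow
cytometry, expressed as relative fluorescence intensity (RFI, % of solvent
control), alongside propidium-iodide viability. A dose range finder first
locates CV75, the concentration giving 75% viability; the main assay then
tests eight 1.2-fold dilutions starting from 1.2 x CV75 (capped at the
solubility-driven maxima of 5000 ug/mL in PBS or 1000 ug/mL in DMSO).

A substance is positive when CD86 RFI >= 150% or CD54 RFI >= 200% at any
concentration with viability >= 50%, in at least two independent runs. For
positives, EC150 (CD86) and EC200 (CD54) are interpolated on the log axis
from the geometric-mean RFI across the qualifying runs, and the minimum
induction threshold (MIT) is the lower of the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dose_response import DoseResponseSeries, ResponseKind, crossing_concentration
from .errors import InsufficientDataError, InvalidInputError, SchemaError

CD86_THRESHOLD = 150.0
CD54_THRESHOLD = 200.0
VIABILITY_MIN = 50.0
#: Starting-concentration caps (ug/mL) by solvent.
STARTING_CAP = {"PBS": 5000.0, "DMSO": 1000.0}
DILUTION_FACTOR = 1.2
N_DOSES = 8


@dataclass(frozen=True)
class HCLATRun:
    """One independent h-CLAT run: CD86/CD54 RFI and viability on a shared grid."""

    cd86_rfi: DoseResponseSeries
    cd54_rfi: DoseResponseSeries
    viability: DoseResponseSeries
    cv75: Optional[float] = None

    def __post_init__(self):
        if not (self.cd86_rfi.same_grid(self.cd54_rfi)
                and self.cd86_rfi.same_grid(self.viability)):
            raise SchemaError("CD86, CD54 and viability series must share one grid")


@dataclass(frozen=True)
class HCLATResult:
    ec150: Optional[float]
    ec200: Optional[float]
    mit: Optional[float]
    positive: bool
    cd86_positive: bool
    cd54_positive: bool
    runs_used: int


def hclat_cv75(viability: DoseResponseSeries) -> Optional[float]:
    """CV75: concentration at 75% viability, interpolated downward on the log
    axis; ``None`` when the substance is not cytotoxic enough to reach it."""
    return crossing_concentration(viability, 75.0, "down", "log")


def hclat_dose_series(cv75: Optional[float], solvent: str) -> list[float]:
    """Main-assay dose series: eight 1.2-fold dilutions from 1.2 x CV75.

    The starting (highest) concentration is 1.2 x CV75 capped at 5000 ug/mL
    (PBS) or 1000 ug/mL (DMSO); a non-cytotoxic substance (``cv75=None``)
    starts at the cap.
    """
    if solvent not in STARTING_CAP:
        raise InvalidInputError(f"unknown solvent {solvent!r}; expected PBS or DMSO")
    cap = STARTING_CAP[solvent]
    if cv75 is None:
        start = cap
    else:
        if cv75 <= 0:
            raise InvalidInputError("CV75 must be positive")
        start = min(DILUTION_FACTOR * cv75, cap)
    return [start / DILUTION_FACTOR ** k for k in range(N_DOSES)]


def _run_qualifies(run: HCLATRun, marker: str, threshold: float) -> bool:
    rfi = np.asarray(getattr(run, marker).responses)
    viab = np.asarray(run.viability.responses)
    return bool(((rfi >= threshold) & (viab >= VIABILITY_MIN)).any())


def _marker_ec(runs: Sequence[HCLATRun], marker: str, threshold: float) -> Optional[float]:
    """EC via log-interpolated crossing on the geometric-mean RFI of the
    qualifying runs, restricted to concentrations with viability >= 50%."""
    grid = np.asarray(runs[0].cd86_rfi.concentrations)
    rfi = np.exp(np.mean(
        [np.log(np.maximum(np.asarray(getattr(r, marker).responses), 1e-9))
         for r in runs], axis=0))
    viab = np.mean([np.asarray(r.viability.responses) for r in runs], axis=0)
    keep = viab >= VIABILITY_MIN
    if keep.sum() < 2:
        return None
    series = DoseResponseSeries(grid[keep], rfi[keep], ResponseKind.RFI_PERCENT,
                                unit="ug/mL")
    return crossing_concentration(series, threshold, "up", "log")


def hclat_evaluate(runs: Sequence[HCLATRun]) -> HCLATResult:
    """Combine >= 2 independent runs into the h-CLAT call and MIT.

    Positivity follows the two-run rule per marker; for each positive marker
    the EC is interpolated from the geometric-mean RFI over the runs that
    qualified for it, and MIT is the minimum of the defined ECs. A negative
    overall call leaves MIT undefined.
    """
    if len(runs) < 2:
        raise InsufficientDataError("h-CLAT evaluation requires at least 2 runs")
    grid = runs[0].cd86_rfi
    if any(not r.cd86_rfi.same_grid(grid) for r in runs[1:]):
        raise SchemaError("all runs must share one concentration grid")

    cd86_runs = [r for r in runs if _run_qualifies(r, "cd86_rfi", CD86_THRESHOLD)]
    cd54_runs = [r for r in runs if _run_qualifies(r, "cd54_rfi", CD54_THRESHOLD)]
    cd86_positive = len(cd86_runs) >= 2
    cd54_positive = len(cd54_runs) >= 2
    positive = cd86_positive or cd54_positive

    ec150 = _marker_ec(cd86_runs, "cd86_rfi", CD86_THRESHOLD) if cd86_positive else None
    ec200 = _marker_ec(cd54_runs, "cd54_rfi", CD54_THRESHOLD) if cd54_positive else None

    defined = [v for v in (ec150, ec200) if v is not None]
    mit = min(defined) if (positive and defined) else None
    return HCLATResult(ec150, ec200, mit, positive, cd86_positive, cd54_positive,
                       len(runs))


def rfi_percent(mfi_treated: float, mfi_treated_isotype: float,
                mfi_solvent: float, mfi_solvent_isotype: float) -> float:
    """Relative fluorescence intensity from raw median fluorescence values:
    100 * (treated - treated isotype) / (solvent - solvent isotype)."""
    denom = mfi_solvent - mfi_solvent_isotype
    if denom <= 0:
        raise InvalidInputError("solvent-control MFI must exceed its isotype control")
    return 100.0 * (mfi_treated - mfi_treated_isotype) / denom
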