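"""KeratinoSens endpoint derivation (keratinocyte Nrf2/ARE reporter assay).

The assay measures luciferase fold induction over solvent control in a
keratinocyte reporter line across a twofold serial dilution series, with cell
viability (MTT) measured in parallel. Endpoints are Imax (average maximum
fold induction at any tested concentration) and EC1.5 (the concentration
producing 1.5-fold induction, interpolated on the log10 concentration axis).

Per TG 442D a run is positive when all of the following hold: Imax >= 1.5;
viability > 70% at the lowest inducing concentration; EC1.5 < 1000 uM; and
the induction increases dose-dependently. "Dose-dependent" is not defined
operationally by the guideline; here it is taken to hold when the tested
concentration immediately above the EC1.5 crossing responds at least as
strongly as the crossing itself, or when the rank trend of induction over
the non-cytotoxic concentrations (viability > 70%) is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .dose_response import DoseResponseSeries, crossing_concentration, interpolate_response
from .errors import SchemaError

#: Fold-induction threshold defining EC1.5.
INDUCTION_THRESHOLD = 1.5
#: Viability (%) that the first inducing concentration must exceed.
VIABILITY_CUTOFF = 70.0
#: Upper bound (uM) on EC1.5 for a positive call.
EC15_MAX_UM = 1000.0


@dataclass(frozen=True)
class KeratinoSensResult:
    imax: float
    ec15: Optional[float]
    viability_at_first_induction: Optional[float]
    dose_dependent: bool
    positive: bool


def _dose_dependent(induction: DoseResponseSeries, viability: DoseResponseSeries,
                    ec15: Optional[float]) -> bool:
    conc = np.asarray(induction.concentrations)
    fold = np.asarray(induction.responses)
    viab = np.asarray(viability.responses)

    if ec15 is not None:
        above = conc > ec15
        if above.any():
            next_fold = fold[above][0]
            at_crossing = interpolate_response(induction, ec15, scale="log")
            if next_fold >= at_crossing:
                return True

    ok = viab > VIABILITY_CUTOFF
    if ok.sum() >= 3 and np.ptp(fold[ok]) > 0:
        rho = stats.spearmanr(conc[ok], fold[ok]).statistic
        return bool(np.isfinite(rho) and rho > 0)
    return False


def keratinosens_evaluate(induction: DoseResponseSeries,
                          viability: DoseResponseSeries,
                          ec15_max: float = EC15_MAX_UM) -> KeratinoSensResult:
    """Derive Imax, EC1.5 and the positivity call from averaged plate series.

    Both series must share the same concentration grid (uM). `induction`
    holds mean fold induction over replicates, `viability` mean MTT viability
    (% of control).
    """
    if not induction.same_grid(viability):
        raise SchemaError("induction and viability series must share one concentration grid")

    fold = np.asarray(induction.responses)
    imax = float(fold.max())
    ec15 = crossing_concentration(induction, INDUCTION_THRESHOLD, "up", "log")

    viability_at_first = None
    first_inducing = next(
        (i for i, f in enumerate(fold) if f >= INDUCTION_THRESHOLD), None)
    if first_inducing is not None:
        viability_at_first = float(viability.responses[first_inducing])

    dose_dep = _dose_dependent(induction, viability, ec15)

    positive = (
        imax >= INDUCTION_THRESHOLD
        and ec15 is not None
        and ec15 < ec15_max
        and viability_at_first is not None
        and viability_at_first > VIABILITY_CUTOFF
        and dose_dep
    )
    return KeratinoSensResult(imax, ec15, viability_at_first, dose_dep, positive)
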