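"""Direct peptide reactivity assay (DPRA) endpoint derivation.

The DPRA quantifies the molecular initiating event of the skin-sensitization
adverse outcome pathway — covalent binding to skin proteins — as percent
depletion of synthetic cysteine- and lysine-containing heptapeptides after
24 h co-incubation, measured by HPLC peak area relative to solvent controls.

Two prediction models from OECD TG 442C are implemented:

* the cysteine/lysine average model: positive if the mean of the two
  depletions (Avg.Lys.Cys) exceeds 6.38%, with reactivity classes
  minimal / low / moderate / high;
* the cysteine-only model, used when the test substance co-elutes with the
  lysine peptide peak (positive above 13.89% cysteine depletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import InvalidInputError, NoValidModelError

#: Positivity cutoff for the cysteine/lysine average model (% depletion).
AVG_CUTOFF = 6.38
#: Positivity cutoff for the cysteine-only model (% depletion).
CYS_ONLY_CUTOFF = 13.89

# Reactivity class bins, upper bounds inclusive, per TG 442C.
_AVG_BINS = ((6.38, "minimal"), (22.62, "low"), (42.47, "moderate"))
_CYS_BINS = ((13.89, "minimal"), (23.09, "low"), (98.24, "moderate"))


class ReactivityClass(str, Enum):
    MINIMAL = "minimal"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


@dataclass(frozen=True)
class DPRAResult:
    cys_depletion: Optional[float]
    lys_depletion: Optional[float]
    avg_lys_cys: Optional[float]
    positive: bool
    reactivity_class: ReactivityClass
    model_used: str  # "cys_lys" | "cys_only"


def percent_depletion(peak_area_sample: float, peak_area_control: float) -> float:
    """Percent peptide depletion relative to the solvent control.

    100 * (1 - sample/control), clamped to [0, 100]; a sample peak larger than
    the control (negative nominal depletion) reports 0.
    """
    if peak_area_control <= 0:
        raise InvalidInputError("control peak area must be positive")
    if peak_area_sample < 0:
        raise InvalidInputError("sample peak area must be non-negative")
    depletion = 100.0 * (1.0 - peak_area_sample / peak_area_control)
    return float(min(100.0, max(0.0, depletion)))


def _classify(value: float, bins, cutoff: float) -> tuple[bool, ReactivityClass]:
    positive = value > cutoff
    for upper, name in bins:
        if value <= upper:
            return positive, ReactivityClass(name)
    return positive, ReactivityClass.HIGH


def dpra_evaluate(cys_depletion: Optional[float],
                  lys_depletion: Optional[float]) -> DPRAResult:
    """Classify peptide reactivity from cysteine/lysine percent depletions.

    Pass ``None`` for a depletion that could not be measured because the test
    substance co-eluted with the peptide peak. With both values the average
    model applies (positive if Avg.Lys.Cys > 6.38%); with only cysteine the
    cysteine-only model applies. With no usable cysteine value no TG 442C
    model applies and :class:`NoValidModelError` is raised.
    """
    for name, v in (("cysteine", cys_depletion), ("lysine", lys_depletion)):
        if v is not None and not (0.0 <= v <= 100.0):
            raise InvalidInputError(f"{name} depletion {v} outside [0, 100]")

    if cys_depletion is None:
        raise NoValidModelError(
            "no prediction model applies without a cysteine depletion value")

    if lys_depletion is None:
        positive, cls = _classify(cys_depletion, _CYS_BINS, CYS_ONLY_CUTOFF)
        return DPRAResult(cys_depletion, None, None, positive, cls, "cys_only")

    avg = 0.5 * (cys_depletion + lys_depletion)
    positive, cls = _classify(avg, _AVG_BINS, AVG_CUTOFF)
    return DPRAResult(cys_depletion, lys_depletion, avg, positive, cls, "cys_lys")
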