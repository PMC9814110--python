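"""Comparison of nonanimal EC3 predictions with in vivo references.

Error metrics (RMSE/MAE on the raw percent scale, plus log10-scale versions
matching the network benchmark convention), GHS concordance tables, the
h-CLAT strong/weak potency category, and the conversion of an EC3 (% w/v) to
an applied dose per skin area (ug/cm2) for comparison against human
no-expected-sensitization-induction levels (NESILs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InvalidInputError

#: % w/v -> ug/cm2 on the mouse ear: x10 (ug/uL) x 25 uL applied / 1 cm2.
DOSE_PER_AREA_FACTOR = 250.0
#: h-CLAT MIT (ug/mL) at or below which a substance is a strong sensitizer.
MIT_STRONG_CUTOFF = 10.0

#: Potency ordering used to label disagreements (higher = more potent call).
_CLASS_POTENCY = {"NC": 0, "1B": 1, "1A": 2}


def _paired(predicted: Sequence[float], reference: Sequence[float]):
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.size == 0 or p.shape != r.shape:
        raise InvalidInputError("predicted and reference must be equal-length and non-empty")
    return p, r


def rmse(predicted: Sequence[float], reference: Sequence[float]) -> float:
    """Root-mean-square error on the raw percent scale."""
    p, r = _paired(predicted, reference)
    return float(np.sqrt(np.mean((p - r) ** 2)))


def mae(predicted: Sequence[float], reference: Sequence[float]) -> float:
    """Mean absolute error on the raw percent scale."""
    p, r = _paired(predicted, reference)
    return float(np.mean(np.abs(p - r)))


def rmse_log10(predicted: Sequence[float], reference: Sequence[float]) -> float:
    """RMSE between log10 EC3 values (the network benchmarking scale)."""
    p, r = _paired(predicted, reference)
    if (p <= 0).any() or (r <= 0).any():
        raise InvalidInputError("log-scale metrics need positive EC3 values")
    return float(np.sqrt(np.mean((np.log10(p) - np.log10(r)) ** 2)))


def ec3_to_dose_per_area(ec3: float) -> float:
    """Convert an LLNA EC3 (% w/v) to applied dose per skin area (ug/cm2)."""
    if ec3 < 0:
        raise InvalidInputError("EC3 must be non-negative")
    return ec3 * DOSE_PER_AREA_FACTOR


def nesil_ratio(dose_per_area: float, nesil: float) -> float:
    """Fold difference between a dose-per-area point of departure and a NESIL."""
    if nesil <= 0:
        raise InvalidInputError("NESIL must be positive")
    if dose_per_area < 0:
        raise InvalidInputError("dose per area must be non-negative")
    return dose_per_area / nesil


def hclat_potency_category(mit: float) -> str:
    """Strong/weak sensitizer category from the h-CLAT minimum induction
    threshold: strong at 10 ug/mL or less, weak above."""
    if mit <= 0:
        raise InvalidInputError("MIT must be positive")
    return "strong" if mit <= MIT_STRONG_CUTOFF else "weak"


def round_sig(value: float, sig: int = 2) -> float:
    """Round to `sig` significant figures (reporting-layer convention)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, -exponent + sig - 1)


@dataclass(frozen=True)
class ConcordanceTable:
    n_shared: int
    n_agree: int
    over_classified: tuple  # predicted more potent than reference
    under_classified: tuple
    unmatched: tuple        # chemicals lacking a reference class

    @property
    def agreement(self) -> float:
        return self.n_agree / self.n_shared


def concordance(pred_classes: Mapping[str, str],
                ref_classes: Mapping[str, str]) -> ConcordanceTable:
    """Pairwise class agreement over the chemicals both maps cover.

    A prediction of a more potent class than the reference (e.g. 1A vs 1B)
    counts as over-classification; chemicals without a reference class are
    listed separately, not scored.
    """
    shared = sorted(set(pred_classes) & set(ref_classes))
    if not shared:
        raise InvalidInputError("no chemicals shared between prediction and reference")
    over, under, agree = [], [], 0
    for chem in shared:
        p, r = pred_classes[chem], ref_classes[chem]
        if p == r:
            agree += 1
        elif _CLASS_POTENCY[p] > _CLASS_POTENCY[r]:
            over.append(chem)
        else:
            under.append(chem)
    unmatched = tuple(sorted(set(pred_classes) - set(ref_classes)))
    return ConcordanceTable(len(shared), agree, tuple(over), tuple(under), unmatched)


@dataclass
class PotencyReport:
    """Per-chemical potency calls plus summary prediction-error metrics.

    `rows` is a list of per-chemical dicts (hazard calls, classes, EC3s with
    CIs, dose-per-area values); `metrics` maps (model variant, approach) to
    {"rmse": ..., "mae": ..., "n": ...} over the chemicals that have both a
    prediction and a reference.
    """

    rows: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    concordance_tables: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "metrics": {f"{v}|{a}": m for (v, a), m in self.metrics.items()},
            "concordance": {
                f"{v}|{a}": {
                    "n_shared": t.n_shared, "n_agree": t.n_agree,
                    "over_classified": list(t.over_classified),
                    "under_classified": list(t.under_classified),
                    "unmatched": list(t.unmatched),
                }
                for (v, a), t in self.concordance_tables.items()
            },
        }


def build_report(predictions: Mapping[str, Mapping[str, "object"]],
                 references: Mapping[str, Mapping[str, "object"]],
                 mits: Optional[Mapping[str, float]] = None,
                 nesils: Optional[Mapping[str, float]] = None) -> PotencyReport:
    """Assemble the potency comparison report.

    Parameters
    ----------
    predictions
        variant -> chemical -> EnsemblePrediction (or any object with
        ``mean_ec3``, ``ci_low``, ``ci_high``).
    references
        approach ("A1"/"A2") -> chemical -> ReferenceEC3.
    mits
        Optional chemical -> h-CLAT MIT (ug/mL) for potency categories.
    nesils
        Optional chemical -> NESIL (ug/cm2) for fold-ratio reporting.
    """
    from .llna import ghs_classify

    report = PotencyReport()
    chemicals = sorted({c for preds in predictions.values() for c in preds})
    for chem in chemicals:
        row: dict = {"chemical": chem}
        if mits and chem in mits:
            row["hclat_mit"] = mits[chem]
            row["hclat_category"] = hclat_potency_category(mits[chem])
        for variant, preds in predictions.items():
            if chem not in preds:
                continue
            p = preds[chem]
            dpa = ec3_to_dose_per_area(p.mean_ec3)
            row[f"{variant}_ec3"] = p.mean_ec3
            row[f"{variant}_ci"] = [p.ci_low, p.ci_high]
            row[f"{variant}_ghs"] = ghs_classify(p.mean_ec3)
            row[f"{variant}_dose_per_area"] = round_sig(dpa, 2)
            if nesils and chem in nesils:
                row[f"{variant}_nesil_ratio"] = round_sig(
                    nesil_ratio(round_sig(dpa, 2), nesils[chem]), 2)
        for approach, refs in references.items():
            if chem in refs:
                ref = refs[chem]
                row[f"ref_{approach}_ec3"] = ref.mean
                row[f"ref_{approach}_ghs"] = ref.ghs_class
        report.rows.append(row)

    for variant, preds in predictions.items():
        pred_classes = {c: ghs_classify(p.mean_ec3) for c, p in preds.items()}
        for approach, refs in references.items():
            shared = sorted(set(preds) & set(refs))
            if not shared:
                continue
            pv = [preds[c].mean_ec3 for c in shared]
            rv = [refs[c].mean for c in shared]
            report.metrics[(variant, approach)] = {
                "rmse": rmse(pv, rv), "mae": mae(pv, rv), "n": len(shared)}
            ref_classes = {c: refs[c].ghs_class for c in shared}
            report.concordance_tables[(variant, approach)] = concordance(
                pred_classes, ref_classes)
    return report
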