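"""Synthetic data with known ground truth for every pipeline stage.

Nothing here mimics assay mechanism; the generators produce the *structure*
the pipeline consumes — endpoint vectors linked monotonically to a true EC3,
LLNA SI curves that cross SI = 3 at a known concentration with lognormal
inter-study variability, and raw assay fixtures (peak areas, plate series,
h-CLAT runs) whose derived endpoints recover prescribed targets — so that
endpoint derivation, training, ensemble prediction and reference aggregation
can all be tested round-trip against known truth.

Default condition choices: true log10 EC3 uniform on [-3.0, 1.3] (spanning
roughly 0.001-20% w/v, the range of published isothiazolinone references);
endpoint links calibrated so generated Avg.Lys.Cys, MIT and Imax bracket the
observed isothiazolinone values (depletions ~50%, MIT ~1-12 ug/mL, Imax in
the low single digits); per-endpoint lognormal noise sigma = 0.2 (log10);
LLNA inter-study coefficient of variation 0.5 on the natural-log scale.

All generators are pure functions of (spec, seed); the master seed spawns
independent named child streams (training / llna / fixtures) so adding a
generator never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dose_response import DoseResponseSeries, ResponseKind
from .errors import InvalidInputError
from .hclat import DILUTION_FACTOR, N_DOSES, hclat_dose_series
from .llna import CHECKLIST_ATTRIBUTES, LLNAStudy

_STREAMS = {"training": 0, "llna": 1, "fixtures": 2}


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of the synthetic study population.

    Endpoint links (all monotone in log10 EC3 = x):

    * Avg.Lys.Cys = 100 / (1 + 10^(depletion_slope * (x - depletion_mid))),
      plus additive normal noise (percent), clipped to (0.1, 100];
    * MIT = 10^(mit_slope * x + mit_intercept) times 10^N(0, noise_sd_log);
    * Imax = 1 + imax_gain * (1 - x / x_max) times 10^N(0, noise_sd_log),
      floored at 1.
    """

    n_chemicals: int = 80
    seed: int = 0
    log10_ec3_range: tuple = (-3.0, 1.3)
    depletion_slope: float = 0.5
    depletion_mid: float = 0.0
    depletion_noise_sd: float = 3.0
    mit_slope: float = 0.5
    mit_intercept: float = 1.0
    imax_gain: float = 3.0
    noise_sd_log: float = 0.2
    test_fraction: float = 0.25
    # LLNA simulation: tested concentrations as multiples of the nominal EC3,
    # SI(c) = 1 + 2 (c / EC3_i)^hill with per-study lognormal EC3_i.
    llna_rel_grid: tuple = (0.25, 0.5, 1.0, 2.0, 4.0)
    hill: float = 1.0
    inter_study_cv: float = 0.5
    si_noise_sd: float = 0.0

    def __post_init__(self):
        if self.log10_ec3_range[0] >= self.log10_ec3_range[1]:
            raise InvalidInputError("log10 EC3 range must be ordered")
        if self.noise_sd_log < 0 or self.depletion_noise_sd < 0 or self.si_noise_sd < 0:
            raise InvalidInputError("noise levels must be non-negative")
        if self.hill <= 0:
            raise InvalidInputError("hill coefficient must be positive")
        if not (0.0 <= self.test_fraction < 1.0):
            raise InvalidInputError("test fraction must be in [0, 1)")


def stream_rng(spec_seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    """Independent deterministic generator for a named child stream."""
    return np.random.default_rng(
        np.random.SeedSequence(spec_seed, spawn_key=(_STREAMS[stream], extra)))


def endpoint_truth(spec: SyntheticSpec, log10_ec3: np.ndarray) -> pd.DataFrame:
    """Noise-free endpoint values implied by the monotone links."""
    x = np.asarray(log10_ec3, dtype=float)
    x_max = spec.log10_ec3_range[1]
    depletion = 100.0 / (1.0 + 10.0 ** (spec.depletion_slope * (x - spec.depletion_mid)))
    mit = 10.0 ** (spec.mit_slope * x + spec.mit_intercept)
    imax = 1.0 + spec.imax_gain * (1.0 - x / x_max)
    return pd.DataFrame({"avg_lys_cys": depletion, "mit_ug_ml": mit,
                         "imax": np.maximum(imax, 1.0)})


def generate_training_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Endpoint vectors plus observed EC3 for `n_chemicals`, split 75/25.

    True log10 EC3 is drawn uniformly; endpoints follow the monotone links
    with the spec's noise. Deterministic given ``spec.seed``.
    """
    rng = stream_rng(spec.seed, "training")
    lo, hi = spec.log10_ec3_range
    x = rng.uniform(lo, hi, size=spec.n_chemicals)
    truth = endpoint_truth(spec, x)

    depletion = truth["avg_lys_cys"].to_numpy() + rng.normal(
        0.0, spec.depletion_noise_sd, size=spec.n_chemicals)
    depletion = np.clip(depletion, 0.1, 100.0)
    mit = truth["mit_ug_ml"].to_numpy() * 10.0 ** rng.normal(
        0.0, spec.noise_sd_log, size=spec.n_chemicals)
    imax = 1.0 + (truth["imax"].to_numpy() - 1.0) * 10.0 ** rng.normal(
        0.0, spec.noise_sd_log, size=spec.n_chemicals)
    imax = np.maximum(imax, 1.0)

    n_test = int(round(spec.test_fraction * spec.n_chemicals))
    split = np.array(["train"] * spec.n_chemicals, dtype=object)
    split[rng.choice(spec.n_chemicals, size=n_test, replace=False)] = "test"

    return pd.DataFrame({
        "chemical": [f"SYN{i + 1:03d}" for i in range(spec.n_chemicals)],
        "avg_lys_cys": depletion,
        "mit_ug_ml": mit,
        "imax": imax,
        "ec3_pct": 10.0 ** x,
        "split": split,
    })


def simulate_llna_study(true_ec3: float, spec: SyntheticSpec, study_seed: int,
                        corrupt_flags: Optional[dict] = None,
                        chemical: str = "SYN", vehicle: str = "acetone") -> LLNAStudy:
    """One simulated LLNA study around a nominal EC3.

    The study-level EC3_i is a mean-preserving lognormal perturbation of
    `true_ec3` (mu = -cv^2/2 so that E[EC3_i] = true_ec3); the SI curve
    SI(c) = 1 + 2 (c / EC3_i)^hill is evaluated on the dose grid
    ``spec.llna_rel_grid x true_ec3`` with optional multiplicative
    measurement noise. With all noise at zero, SI(true_ec3) = 3 exactly on
    the grid. Checklist flags default to all true; `corrupt_flags`
    overrides individual attributes for screen testing.
    """
    if true_ec3 <= 0:
        raise InvalidInputError("true EC3 must be positive")
    rng = stream_rng(spec.seed, "llna", extra=study_seed)
    cv = spec.inter_study_cv
    ec3_i = true_ec3 * np.exp(rng.normal(-0.5 * cv * cv, cv)) if cv > 0 else true_ec3
    conc = np.asarray(spec.llna_rel_grid) * true_ec3
    si = 1.0 + 2.0 * (conc / ec3_i) ** spec.hill
    if spec.si_noise_sd > 0:
        si = si * np.exp(rng.normal(0.0, spec.si_noise_sd, size=si.size))
    flags = {attr: True for attr in CHECKLIST_ATTRIBUTES}
    if corrupt_flags:
        flags.update(corrupt_flags)
    series = DoseResponseSeries(conc, si, ResponseKind.STIMULATION_INDEX, unit="% w/v")
    return LLNAStudy(chemical=chemical, series=series, vehicle=vehicle,
                     acceptability_flags=flags, source=f"sim:{study_seed}")


def generate_assay_fixtures(chemical_truth: pd.DataFrame,
                            spec: SyntheticSpec) -> dict:
    """Raw assay CSV fixtures whose derived endpoints recover given targets.

    `chemical_truth` needs columns ``chemical``, ``avg_lys_cys``, ``ec15_um``,
    ``imax``, ``cv75_ug_ml``, ``mit_ug_ml`` and optionally ``solvent``
    (default DMSO). Returns ``{"dpra": ..., "keratinosens": ..., "hclat":
    ..., "truth": ...}`` DataFrames matching the documented CSV schemas.
    Infeasible targets (e.g. a MIT outside the 1.2-fold dose window implied
    by CV75) are flagged in the truth manifest rather than silently shifted.
    """
    dpra_rows, ks_rows, hclat_rows, truth_rows = [], [], [], []
    control_area = 1000.0

    for _, row in chemical_truth.iterrows():
        chem = row["chemical"]
        solvent = row.get("solvent", "DMSO")
        feasible = True

        # DPRA: peak areas reproducing the target depletion on both peptides.
        for replicate in (1, 2, 3):
            for peptide in ("cys", "lys"):
                dpra_rows.append({
                    "chemical": chem, "replicate": replicate, "peptide": peptide,
                    "area_sample": control_area * (1.0 - row["avg_lys_cys"] / 100.0),
                    "area_control": control_area, "coeluted": False,
                })

        # KeratinoSens: 12 twofold dilutions from 2000 uM; log-logistic
        # induction hitting 1.5-fold at the target EC1.5, plateau at Imax.
        conc = 2000.0 / 2.0 ** np.arange(12)[::-1]
        ec15, imax = float(row["ec15_um"]), float(row["imax"])
        if not (conc[0] < ec15 < conc[-1]):
            feasible = False
        # fold(c) = 1 + (imax - 1) * s / (1 + s), s = (c / c50)^p; calibrated
        # so fold(ec15) = 1.5 exactly.
        p = 2.0
        target = 0.5 / (imax - 1.0) if imax > 1.5 else 0.5
        c50 = ec15 * (target / (1.0 - target)) ** (-1.0 / p) if target < 1 else ec15
        s = (conc / c50) ** p
        fold = 1.0 + (imax - 1.0) * s / (1.0 + s)
        for c, f in zip(conc, fold):
            for repetition in (1, 2):
                ks_rows.append({
                    "chemical": chem, "plate": 1, "repetition": repetition,
                    "conc_uM": c, "fold_induction": f, "viability_pct": 95.0,
                })

        # h-CLAT: dose series from CV75, viability hitting 75% at CV75 and
        # CD86 RFI hitting 150% at the target MIT; CD54 stays below 200%.
        cv75, mit = float(row["cv75_ug_ml"]), float(row["mit_ug_ml"])
        doses = np.asarray(hclat_dose_series(cv75, solvent))[::-1]  # ascending
        if not (doses[0] <= mit <= doses[-1]):
            feasible = False
        viability = 100.0 / (1.0 + (1.0 / 3.0) * (doses / cv75) ** 2)
        cd86 = 100.0 + 50.0 * (doses / mit) ** 1.5
        cd54 = 100.0 + 60.0 * (doses / mit) ** 0.5
        for run in (1, 2):
            for d, v, c86, c54 in zip(doses, viability, cd86, cd54):
                hclat_rows.append({
                    "chemical": chem, "run": run, "conc_ug_ml": d,
                    "cd86_rfi": c86, "cd54_rfi": min(c54, 195.0),
                    "viability_pct": v,
                })

        truth_rows.append({**{k: row[k] for k in
                              ("chemical", "avg_lys_cys", "ec15_um", "imax",
                               "cv75_ug_ml", "mit_ug_ml")},
                           "solvent": solvent, "feasible": feasible})

    return {
        "dpra": pd.DataFrame(dpra_rows),
        "keratinosens": pd.DataFrame(ks_rows),
        "hclat": pd.DataFrame(hclat_rows),
        "truth": pd.DataFrame(truth_rows),
    }


def default_fixture_truth(spec: SyntheticSpec, n: int = 4) -> pd.DataFrame:
    """A small feasible truth table for fixture generation, drawn from the
    fixtures stream."""
    rng = stream_rng(spec.seed, "fixtures")
    mit = 10.0 ** rng.uniform(0.0, 1.0, size=n)  # 1-10 ug/mL
    return pd.DataFrame({
        "chemical": [f"FIX{i + 1:02d}" for i in range(n)],
        "avg_lys_cys": rng.uniform(30.0, 60.0, size=n),
        "ec15_um": 10.0 ** rng.uniform(0.5, 2.0, size=n),
        "imax": rng.uniform(2.5, 5.0, size=n),
        "cv75_ug_ml": mit * rng.uniform(1.05, 1.9, size=n),
        "mit_ug_ml": mit,
        "solvent": "DMSO",
    })
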