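"""CSV input schemas and endpoint derivation from raw tables.

Schema version 1. All inputs are plain CSV:

* ``dpra.csv`` — chemical, replicate, peptide (cys|lys), area_sample,
  area_control, coeluted (bool);
* ``keratinosens.csv`` — chemical, plate, repetition, conc_uM,
  fold_induction, viability_pct;
* ``hclat.csv`` — chemical, run, conc_ug_ml, cd86_rfi, cd54_rfi,
  viability_pct;
* ``llna_studies.csv`` — chemical, study_id, vehicle, conc_pct, si, source,
  plus one boolean column per quality-checklist attribute;
* ``training_table.csv`` — chemical, avg_lys_cys, mit_ug_ml, imax, ec3_pct,
  split.

Reading functions aggregate replicates (mean peak areas / fold inductions,
per-run h-CLAT series) and hand the resulting series to the endpoint
calculators; per-chemical results are returned as plain dicts ready for JSON
serialization.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dose_response import DoseResponseSeries, ResponseKind
from .dpra import dpra_evaluate, percent_depletion
from .errors import SchemaError
from .hclat import HCLATRun, hclat_evaluate
from .keratinosens import keratinosens_evaluate
from .llna import CHECKLIST_ATTRIBUTES, LLNAStudy

SCHEMA_VERSION = 1

_REQUIRED = {
    "dpra": {"chemical", "replicate", "peptide", "area_sample", "area_control",
             "coeluted"},
    "keratinosens": {"chemical", "plate", "repetition", "conc_uM",
                     "fold_induction", "viability_pct"},
    "hclat": {"chemical", "run", "conc_ug_ml", "cd86_rfi", "cd54_rfi",
              "viability_pct"},
    "llna": {"chemical", "study_id", "vehicle", "conc_pct", "si"},
}


def _check_columns(df: pd.DataFrame, schema: str) -> None:
    missing = _REQUIRED[schema] - set(df.columns)
    if missing:
        raise SchemaError(f"{schema} table missing column(s) {sorted(missing)}")


def read_dpra(path_or_df) -> dict:
    """Per-chemical DPRA results from a raw peak-area table.

    Replicate depletions are computed per row and averaged per peptide; a
    peptide flagged co-eluted in any replicate is treated as unmeasurable.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    _check_columns(df, "dpra")
    results = {}
    for chemical, group in df.groupby("chemical"):
        depletions: dict[str, Optional[float]] = {}
        for peptide, rows in group.groupby("peptide"):
            if peptide not in ("cys", "lys"):
                raise SchemaError(f"unknown peptide {peptide!r}")
            if rows["coeluted"].astype(bool).any():
                depletions[peptide] = None
            else:
                depletions[peptide] = float(np.mean([
                    percent_depletion(r.area_sample, r.area_control)
                    for r in rows.itertuples()]))
        results[chemical] = dpra_evaluate(depletions.get("cys"),
                                          depletions.get("lys"))
    return results


def read_keratinosens(path_or_df) -> dict:
    """Per-chemical KeratinoSens results from plate-level fold inductions.

    Fold induction and viability are averaged over plates/repetitions at each
    concentration before endpoint derivation.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    _check_columns(df, "keratinosens")
    results = {}
    for chemical, group in df.groupby("chemical"):
        mean = group.groupby("conc_uM")[["fold_induction", "viability_pct"]].mean()
        mean = mean.sort_index()
        induction = DoseResponseSeries(mean.index, mean["fold_induction"],
                                       ResponseKind.FOLD_INDUCTION, unit="uM")
        viability = DoseResponseSeries(mean.index, mean["viability_pct"],
                                       ResponseKind.VIABILITY_PERCENT, unit="uM")
        results[chemical] = keratinosens_evaluate(induction, viability)
    return results


def read_hclat(path_or_df) -> dict:
    """Per-chemical h-CLAT results from run-level RFI/viability tables."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    _check_columns(df, "hclat")
    results = {}
    for chemical, group in df.groupby("chemical"):
        runs = []
        for _, rows in group.groupby("run"):
            rows = rows.sort_values("conc_ug_ml")
            conc = rows["conc_ug_ml"].to_numpy()
            runs.append(HCLATRun(
                cd86_rfi=DoseResponseSeries(conc, rows["cd86_rfi"],
                                            ResponseKind.RFI_PERCENT, "ug/mL"),
                cd54_rfi=DoseResponseSeries(conc, rows["cd54_rfi"],
                                            ResponseKind.RFI_PERCENT, "ug/mL"),
                viability=DoseResponseSeries(conc, rows["viability_pct"],
                                             ResponseKind.VIABILITY_PERCENT, "ug/mL"),
            ))
        results[chemical] = hclat_evaluate(runs)
    return results


def read_llna_studies(path_or_df) -> list:
    """LLNA studies from a long-format concentration/SI table.

    Checklist columns absent from the table default to True (curated input);
    duplicate studies — same chemical and identical SI vector — are dropped,
    keeping the first occurrence.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    _check_columns(df, "llna")
    studies, seen = [], set()
    for (chemical, study_id), rows in df.groupby(["chemical", "study_id"]):
        rows = rows.sort_values("conc_pct")
        flags = {}
        for attr in CHECKLIST_ATTRIBUTES:
            flags[attr] = bool(rows[attr].iloc[0]) if attr in rows.columns else True
        series = DoseResponseSeries(rows["conc_pct"], rows["si"],
                                    ResponseKind.STIMULATION_INDEX, "% w/v")
        dedup_key = (chemical, tuple(np.round(series.responses, 6)))
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        studies.append(LLNAStudy(
            chemical=chemical, series=series,
            vehicle=str(rows["vehicle"].iloc[0]),
            acceptability_flags=flags,
            source=str(rows["source"].iloc[0]) if "source" in rows.columns else str(study_id)))
    return studies


def read_training_table(path_or_df) -> pd.DataFrame:
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    return df


def endpoint_results_to_json(dpra_results: dict, ks_results: dict,
                             hclat_results: dict, path=None) -> dict:
    """Merge per-assay results into one JSON-ready per-chemical record."""
    chemicals = sorted(set(dpra_results) | set(ks_results) | set(hclat_results))
    out = {"schema_version": SCHEMA_VERSION, "chemicals": {}}
    for chem in chemicals:
        record: dict = {}
        if chem in dpra_results:
            r = dpra_results[chem]
            record["dpra"] = {
                "cys_depletion": r.cys_depletion, "lys_depletion": r.lys_depletion,
                "avg_lys_cys": r.avg_lys_cys, "positive": r.positive,
                "reactivity_class": r.reactivity_class.value,
                "model_used": r.model_used}
        if chem in ks_results:
            r = ks_results[chem]
            record["keratinosens"] = {
                "imax": r.imax, "ec15_um": r.ec15,
                "viability_at_first_induction": r.viability_at_first_induction,
                "dose_dependent": r.dose_dependent, "positive": r.positive}
        if chem in hclat_results:
            r = hclat_results[chem]
            record["hclat"] = {
                "ec150": r.ec150, "ec200": r.ec200, "mit": r.mit,
                "positive": r.positive, "runs_used": r.runs_used}
        out["chemicals"][chem] = record
    if path is not None:
        Path(path).write_text(json.dumps(out, indent=1))
    return out
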