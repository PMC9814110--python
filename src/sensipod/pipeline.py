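"""End-to-end orchestration: endpoints -> references -> ensembles -> report.

A run is declared by a :class:`RunConfig` (constructable from YAML). Every
output directory carries a ``manifest.json`` with the package version, the
configuration hash and the master seed, so a rerun with the same
configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .ann import ANNConfig, ANNEnsemble, VARIANT_FEATURES
from .errors import PipelineStageError, SchemaError
from .io import (endpoint_results_to_json, read_dpra, read_hclat,
                 read_keratinosens, read_llna_studies, read_training_table)
from .llna import (approach1_select, approach2_aggregate, ec3_from_study,
                   screen_study)
from .potency import build_report
from .synthetic import (SyntheticSpec, default_fixture_truth,
                        generate_assay_fixtures, generate_training_table,
                        simulate_llna_study, stream_rng)

logger = logging.getLogger("sensipod")


@dataclass
class RunConfig:
    """Declarative pipeline run configuration.

    Either point the raw-assay / LLNA / training paths at CSV files or set
    ``simulate`` to generate everything synthetically under the master seed.
    """

    output_dir: str = "sensipod_out"
    seed: int = 0
    variants: tuple = ("D_hC", "D_hC_KS")
    approaches: tuple = ("A1", "A2")
    n_runs: int = 100
    iterations: int = 10_000
    simulate: bool = True
    n_chemicals: int = 40
    dpra_csv: Optional[str] = None
    keratinosens_csv: Optional[str] = None
    hclat_csv: Optional[str] = None
    llna_csv: Optional[str] = None
    training_csv: Optional[str] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config key(s) {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("variants", "approaches"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _log(stage: str, message: str, **fields) -> None:
    extra = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("stage=%s %s %s", stage, message, extra)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write artifacts to ``config.output_dir``.

    Stages: synthesize or load inputs; derive assay endpoints; curate LLNA
    references under the selected approaches; train one ensemble per network
    variant and predict each chemical's EC3; assemble the potency report.
    Returns the report as a dict (also written as JSON).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSpec(n_chemicals=config.n_chemicals, seed=config.seed)

    # --- stage: inputs -----------------------------------------------------
    try:
        if config.simulate:
            _log("inputs", "simulating fixtures", seed=config.seed)
            training = generate_training_table(spec)
            truth = default_fixture_truth(spec, n=min(6, config.n_chemicals))
            fixtures = generate_assay_fixtures(truth, spec)
            dpra_df, ks_df, hclat_df = (fixtures["dpra"], fixtures["keratinosens"],
                                        fixtures["hclat"])
            rng = stream_rng(config.seed, "llna")
            llna_studies = []
            for i, row in truth.iterrows():
                true_ec3 = float(row["mit_ug_ml"]) / 10.0  # plausible % scale
                for j in range(3):
                    llna_studies.append(simulate_llna_study(
                        true_ec3, spec, study_seed=1000 * i + j,
                        chemical=row["chemical"]))
        else:
            if not config.training_csv:
                raise SchemaError("training_csv required when simulate is false")
            training = read_training_table(config.training_csv)
            dpra_df = pd.read_csv(config.dpra_csv) if config.dpra_csv else None
            ks_df = pd.read_csv(config.keratinosens_csv) if config.keratinosens_csv else None
            hclat_df = pd.read_csv(config.hclat_csv) if config.hclat_csv else None
            llna_studies = (read_llna_studies(config.llna_csv)
                            if config.llna_csv else [])
        for variant in config.variants:
            missing = [f for f in VARIANT_FEATURES[variant]
                       if f not in training.columns]
            if missing:
                raise SchemaError(
                    f"variant {variant} requires training column(s) {missing}")
    except SchemaError:
        raise
    except Exception as exc:  # pragma: no cover - diagnostic wrapper
        raise PipelineStageError("inputs", str(exc)) from exc

    # --- stage: endpoints --------------------------------------------------
    endpoints_json = {}
    if dpra_df is not None and ks_df is not None and hclat_df is not None:
        _log("endpoints", "deriving assay endpoints")
        dpra_res = read_dpra(dpra_df)
        ks_res = read_keratinosens(ks_df)
        hclat_res = read_hclat(hclat_df)
        endpoints_json = endpoint_results_to_json(
            dpra_res, ks_res, hclat_res, path=out / "endpoints.json")
    mits = {c: r["hclat"]["mit"] for c, r in
            endpoints_json.get("chemicals", {}).items()
            if r.get("hclat", {}).get("mit")}

    # --- stage: references -------------------------------------------------
    references: dict = {}
    if llna_studies:
        _log("reference", "curating LLNA references", n_studies=len(llna_studies))
        by_chem: dict = {}
        for study in llna_studies:
            est = screen_study(study, ec3_from_study(study.series))
            by_chem.setdefault(study.chemical, []).append((study, est))
        for approach in config.approaches:
            refs = {}
            for chem, pairs in by_chem.items():
                try:
                    if approach == "A1":
                        refs[chem] = approach1_select(pairs)
                    else:
                        values = [e.value for _, e in pairs
                                  if e.accepted and e.value is not None]
                        if values:
                            refs[chem] = approach2_aggregate(values)
                except Exception as exc:
                    _log("reference", f"no {approach} reference for {chem}: {exc}")
            references[approach] = refs

    # --- stage: train / predict --------------------------------------------
    predictions: dict = {}
    pred_rows = []
    for variant in config.variants:
        _log("train", "fitting ensemble", variant=variant, n_runs=config.n_runs)
        ann_cfg = ANNConfig(variant=variant, iterations=config.iterations,
                            seed=config.seed)
        ensemble = ANNEnsemble.fit(training, ann_cfg, n_runs=config.n_runs)
        preds = {}
        targets = (endpoints_json.get("chemicals") or
                   {c: None for c in training["chemical"]})
        for chem in targets:
            if endpoints_json:
                rec = endpoints_json["chemicals"][chem]
                vec = {"avg_lys_cys": rec.get("dpra", {}).get("avg_lys_cys"),
                       "mit_ug_ml": rec.get("hclat", {}).get("mit"),
                       "imax": rec.get("keratinosens", {}).get("imax")}
            else:
                row = training[training["chemical"] == chem].iloc[0]
                vec = {f: row[f] for f in VARIANT_FEATURES[variant]}
            if any(vec.get(f) is None for f in VARIANT_FEATURES[variant]):
                _log("predict", f"skipping {chem}: missing endpoint", variant=variant)
                continue
            preds[chem] = ensemble.predict(vec)
            pred_rows.append({"chemical": chem, "variant": variant,
                              "mean_ec3": preds[chem].mean_ec3,
                              "ci_low": preds[chem].ci_low,
                              "ci_high": preds[chem].ci_high,
                              "n_runs": preds[chem].n_runs})
        predictions[variant] = preds
    pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)

    # --- stage: evaluate ---------------------------------------------------
    _log("evaluate", "building potency report")
    report = build_report(predictions, references, mits=mits or None)
    report_dict = report.to_dict()
    result = {
        "manifest": {
            "tool": "sensipod", "version": __version__,
            "config_hash": config.config_hash(), "seed": config.seed,
            "config": asdict(config),
        },
        "report": report_dict,
    }
    (out / "report.json").write_text(json.dumps(result, indent=1, default=str))
    (out / "manifest.json").write_text(json.dumps(result["manifest"], indent=1,
                                                  default=str))
    return result
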