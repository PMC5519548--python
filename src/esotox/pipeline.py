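"""End-to-end experiment wiring with config echo, logging and provenance.

Stages: generate (or read) cohort -> expansion quantification -> low-dose
exclusion and clustering -> feature assembly (with and without the
radiosensitivity tag) -> repeated cross-validation of both model families ->
comparison report. Every run writes a manifest with the echoed configuration,
content hashes of all outputs, per-stage wall times and recorded warnings.
Tabular outputs are CSV; the summary is versioned JSON written with sorted
keys so equal-seed runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, expansion, features, modelling, simulate

__all__ = ["RunConfig", "RunManifest", "StageError", "run_pipeline", "load_config"]

log = logging.getLogger("esotox")

SUMMARY_SCHEMA = "esotox-summary/1"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    generator: simulate.GeneratorConfig = field(default_factory=simulate.GeneratorConfig)
    cluster: clustering.ClusterConfig = field(default_factory=clustering.ClusterConfig)
    cv: modelling.CVConfig = field(default_factory=modelling.CVConfig)
    cohort_path: str | None = None  # read an existing cohort instead of generating
    target_fraction: int = 30
    subvolume_edge_mm: float = 20.0
    out_dir: str = "esotox_run"


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    outputs: dict[str, str]  # file name -> sha256
    timings: dict[str, float]
    warnings: list[str]


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, dict):
            return {str(k): clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return clean(d)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration (missing sections use defaults)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen = raw.get("generator", {})
    if "grade_model" in gen:
        gen["grade_model"] = simulate.GradeModel(**gen["grade_model"])
    for tup_field in ("weekly_scan_fractions", "low_dose_range", "radius_range_mm"):
        if gen.get(tup_field) is not None:
            gen[tup_field] = tuple(gen[tup_field])
    if "class_dose_ranges" in gen:
        gen["class_dose_ranges"] = {
            k: tuple(v) for k, v in gen["class_dose_ranges"].items()
        }
    if "prescription_mix" in gen:
        gen["prescription_mix"] = {int(k): v for k, v in gen["prescription_mix"].items()}
    return RunConfig(
        generator=simulate.GeneratorConfig(**gen),
        cluster=clustering.ClusterConfig(**raw.get("cluster", {})),
        cv=modelling.CVConfig(**raw.get("cv", {})),
        **{
            k: raw[k]
            for k in ("cohort_path", "target_fraction", "subvolume_edge_mm", "out_dir")
            if k in raw
        },
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, timings: dict, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # fail fast with stage context
        raise StageError(name, str(exc)) from exc
    timings[name] = round(time.perf_counter() - t0, 3)
    log.info("stage %-10s done in %.2fs", name, timings[name])
    return out


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full experiment and write all stage outputs under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings: list[str] = []

    if config.cohort_path:
        cohort = _stage("read_cohort", timings, simulate.read_cohort, config.cohort_path)
    else:
        cohort = _stage("generate", timings, simulate.generate_cohort, config.generator)

    responses = _stage(
        "expansion",
        timings,
        expansion.quantify_cohort,
        cohort,
        config.target_fraction,
        config.subvolume_edge_mm,
    )
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in responses],
            "scan_fraction": [r.scan_fraction for r in responses],
            "center_slice": [r.center_slice for r in responses],
            "mean_expansion_pct": [r.mean_expansion for r in responses],
            "mean_delivered_dose_gy": [r.mean_delivered_dose for r in responses],
        }
    ).to_csv(out / "expansion_responses.csv", index=False)

    result = _stage("cluster", timings, clustering.cluster_responses,
                    responses, config.cluster)
    if result.assumption_check.get("status") == "warn":
        warnings.extend(result.assumption_check["warnings"])
    by_id = {r.patient_id: r for r in responses}
    pd.DataFrame(
        {
            "patient_id": result.patient_ids,
            "mean_delivered_dose_gy": [by_id[p].mean_delivered_dose for p in result.patient_ids],
            "mean_expansion_pct": [by_id[p].mean_expansion for p in result.patient_ids],
            "cluster": result.labels,
            "role": [result.role_map[int(c)] for c in result.labels],
            "tag": result.tag,
        }
    ).to_csv(out / "clusters.csv", index=False)
    with open(out / "cluster_summary.json", "w") as fh:
        json.dump(
            {
                "centroids_dose_expansion": result.centroids.tolist(),
                "role_map": {str(k): v for k, v in result.role_map.items()},
                "assumption_check": result.assumption_check,
                "n_excluded": len(result.excluded_ids),
                "excluded_ids": list(result.excluded_ids),
            },
            fh,
            indent=1,
            sort_keys=True,
        )

    retained_ids = set(result.patient_ids)
    analyzed = [s for s in cohort if s.patient_id in retained_ids]
    tag = clustering.make_tag(result, [s.patient_id for s in analyzed])
    grades = np.array([s.max_grade for s in analyzed])

    fm_with = _stage("features", timings, features.assemble_features, analyzed, tag)
    fm_without = features.assemble_features(analyzed)
    fm_with.values.to_csv(out / "features_with_tag.csv")
    fm_without.values.to_csv(out / "features_without_tag.csv")

    res_with = _stage("model_with_tag", timings, modelling.repeated_cv,
                      fm_with, grades, config.cv)
    res_without = _stage("model_without_tag", timings, modelling.repeated_cv,
                         fm_without, grades, config.cv)
    for name, res in (("with_tag", res_with), ("without_tag", res_without)):
        pd.DataFrame(
            {
                "iteration": [r.iteration for r in res],
                "auc_training": [r.auc_training for r in res],
                "auc_test": [r.auc_test for r in res],
                "brier_test": [r.brier_test for r in res],
                "scaled_brier_test_pct": [r.scaled_brier_test for r in res],
                "chosen_lambda": [r.chosen_lambda for r in res],
                "selected_predictors": [
                    ";".join(map(str, r.selected_predictors)) for r in res
                ],
            }
        ).to_csv(out / f"cv_iterations_{name}.csv", index=False)

    report = _stage("report", timings, modelling.compare_families, res_with, res_without)
    rec_rows = []
    for fam, counts in report.recurrence.items():
        for idx, count in sorted(counts.items()):
            rec_rows.append(
                {
                    "family": fam,
                    "predictor_index": idx,
                    "predictor": features.PREDICTOR_CATALOGUE[idx],
                    "recurrence": count,
                }
            )
    pd.DataFrame(rec_rows).to_csv(out / "recurrence.csv", index=False)

    summary = {
        "schema": SUMMARY_SCHEMA,
        "n_patients": len(cohort),
        "n_analyzed": len(analyzed),
        "n_excluded": len(result.excluded_ids),
        "summary": report.summary,
        "auc_test_paired_ttest": {
            "statistic": report.auc_test_ttest[0],
            "p_value": report.auc_test_ttest[1],
        },
        "auc_training_paired_ttest": {
            "statistic": report.auc_training_ttest[0],
            "p_value": report.auc_training_ttest[1],
        },
        "top_predictors": report.top_predictors,
        "warnings": warnings,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    outputs = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config={
            "generator": _asdict(config.generator),
            "cluster": _asdict(config.cluster),
            "cv": {k: v for k, v in _asdict(config.cv).items() if k != "lambda_grid"},
            "target_fraction": config.target_fraction,
            "subvolume_edge_mm": config.subvolume_edge_mm,
        },
        seeds={
            "generator": config.generator.seed,
            "cluster": config.cluster.seed,
            "cv": config.cv.seed,
        },
        outputs=outputs,
        timings=timings,
        warnings=warnings,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=1, sort_keys=True)
    return manifest
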