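"""End-to-end pipeline: (optional) simulate -> eligibility -> classify ->
validate, with artifacts and a run-metadata block written to an output
directory."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .algorithms import (
    build_case_finding_algorithm,
    build_control_algorithm,
    classify_cohort,
    results_to_frame,
)
from .claims import load_cohort, select_eligible
from .criteria import CodeRegistry
from .errors import NsclcFinderError
from .simulate import SyntheticCohortConfig, cohort_to_csv, generate_cohort
from .stats import accuracy_measures, confusion_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    claims_path: str | None = None
    enrollment_path: str | None = None
    patients_path: str | None = None
    labels_path: str | None = None
    simulate: bool = False
    n_patients: int = 1353
    seed: int = 0
    algorithm: str = "case_finding"  # case_finding | control | path to YAML
    concepts_path: str | None = None
    intake_start: str = "2014-06-01"
    intake_end: str = "2015-10-31"
    min_age: float = 18
    pre_months: int = 3
    post_months: int = 3
    gap_tolerance_days: int = 0
    default_label: str | None = None
    zero_cell_correction: str = "none"

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def resolve_algorithm(name: str, registry: CodeRegistry, default_label: str | None = None):
    overrides = {"default_label": default_label} if default_label else {}
    if name == "case_finding":
        return build_case_finding_algorithm(registry=registry, **overrides)
    if name == "control":
        return build_control_algorithm(registry=registry, **overrides)
    path = Path(name)
    if path.exists():
        return build_case_finding_algorithm(config_path=path, registry=registry, **overrides)
    raise NsclcFinderError(
        f"unknown algorithm {name!r}: expected 'case_finding', 'control' or a YAML path"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns a dict of artifact paths.

    Artifacts: predictions.csv, accuracy_report.json, attrition.json and
    run_metadata.json (package version, seed, config hash) in ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = CodeRegistry.from_yaml(config.concepts_path)

    if config.simulate:
        sim_config = SyntheticCohortConfig(
            n_patients=config.n_patients,
            seed=config.seed,
            intake_start=config.intake_start,
            intake_end=config.intake_end,
        )
        cohort = generate_cohort(sim_config, registry=registry)
        paths = cohort_to_csv(cohort, out / "cohort")
        config.claims_path = str(paths["claims"])
        config.enrollment_path = str(paths["enrollment"])
        config.patients_path = str(paths["patients"])
        config.labels_path = str(paths["labels"])

    missing = [
        name for name, p in (
            ("claims", config.claims_path), ("enrollment", config.enrollment_path),
            ("patients", config.patients_path), ("labels", config.labels_path),
        ) if p is None or not Path(p).exists()
    ]
    if missing:
        raise NsclcFinderError(f"missing input file(s): {', '.join(missing)}")

    claims, spans, patients, labels = load_cohort(
        config.claims_path, config.enrollment_path,
        config.patients_path, config.labels_path,
    )
    eligible, attrition = select_eligible(
        patients, spans, config.intake_start, config.intake_end,
        labels=labels, min_age=config.min_age,
        pre_months=config.pre_months, post_months=config.post_months,
        gap_tolerance_days=config.gap_tolerance_days,
    )
    algorithm = resolve_algorithm(config.algorithm, registry, config.default_label)
    results = classify_cohort(eligible, claims, algorithm, registry)
    pred_df = results_to_frame(results)
    pred_df.to_csv(out / "predictions.csv", index=False)

    labels_eligible = labels[labels["patient_id"].isin(set(eligible["patient_id"]))]
    ct = confusion_table(
        pred_df.set_index("patient_id")["predicted"],
        labels_eligible.set_index("patient_id")["subtype"],
    )
    acc = accuracy_measures(ct, zero_cell_correction=config.zero_cell_correction)
    (out / "accuracy_report.json").write_text(json.dumps(acc.to_dict(), indent=2))
    (out / "attrition.json").write_text(json.dumps(attrition, indent=2))
    (out / "run_metadata.json").write_text(json.dumps({
        "package": "nsclcfinder",
        "version": __version__,
        "seed": config.seed,
        "algorithm": algorithm.name,
        "config_hash": config.digest(),
    }, indent=2))
    logger.info("pipeline complete: %s", out)
    return {
        "predictions": out / "predictions.csv",
        "accuracy_report": out / "accuracy_report.json",
        "attrition": out / "attrition.json",
        "metadata": out / "run_metadata.json",
    }
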