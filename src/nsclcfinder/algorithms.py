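"""The NSCLC case-finding and control algorithms as classification policies
over criterion matches.

Two policies exist:

``exclusion_first``
    Any matched SCLC-indicative regimen vetoes the NSCLC label (the patient
    is classified SCLC); otherwise any matched NSCLC-indicative criterion
    yields NSCLC; otherwise the default label.  This is the case-finding
    algorithm's reading: the exclusion criteria exist precisely to remove
    SCLC-treated patients, so they take precedence when a patient matches
    rules of both roles.

``inclusion_only``
    Any matched inclusion criterion yields NSCLC; exclusion-role criteria
    are ignored.  This is the control algorithm, which pools the
    guideline-recommended treatments for both subtypes as inclusion rows.

Classification depends only on which criteria matched, never on how many
claims support a match.  Each result records the policy branch that fired
(``decisive_rule``) for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .criteria import (
    CodeRegistry,
    Criterion,
    CriterionMatch,
    evaluate_all,
    load_criteria_yaml,
)
from .errors import ConfigurationError, ContractError, ValidationError

logger = logging.getLogger(__name__)

POLICIES = ("exclusion_first", "inclusion_only")
LABELS = ("NSCLC", "SCLC", "UNCLASSIFIED")


@dataclass
class AlgorithmDefinition:
    """A named rule set plus the policy that turns matches into a label."""

    name: str
    criteria: list
    policy: str
    default_label: str = "SCLC"
    eval_window: tuple = (90, 90)  # days before / after index

    def __post_init__(self):
        if self.policy not in POLICIES:
            raise ValidationError(f"unknown policy {self.policy!r}")
        if self.default_label not in LABELS:
            raise ValidationError(f"unknown default label {self.default_label!r}")
        if self.policy == "exclusion_first" and not any(
            c.role == "SCLC_exclusion" for c in self.criteria
        ):
            raise ValidationError(
                "exclusion_first policy requires at least one SCLC_exclusion criterion"
            )

    @property
    def exclusion_criteria(self) -> list:
        return [c for c in self.criteria if c.role == "SCLC_exclusion"]

    @property
    def inclusion_criteria(self) -> list:
        return [c for c in self.criteria if c.role == "NSCLC_inclusion"]


@dataclass
class ClassificationResult:
    patient_id: str
    predicted: str
    matched_criteria: list = field(default_factory=list)
    decisive_rule: str = ""


def _build_from_config(
    bundled_name: str,
    config_path: str | Path | None,
    registry: CodeRegistry | None,
    **overrides,
) -> AlgorithmDefinition:
    if config_path is None:
        text = resources.files("nsclcfinder.data").joinpath(bundled_name).read_text()
        raw = load_criteria_yaml(text)
    else:
        raw = load_criteria_yaml(config_path)
    combo_default = raw.get("combo_window_days", 21)
    criteria = [
        Criterion(
            name=c["name"],
            role=c["role"],
            components=tuple(c["components"]),
            combo_window_days=int(c.get("combo_window_days", combo_default)),
        )
        for c in raw["criteria"]
    ]
    registry = registry or CodeRegistry.from_yaml()
    for criterion in criteria:
        for concept in criterion.components:
            if concept not in registry:
                raise ConfigurationError(
                    f"criterion {criterion.name!r} references concept {concept!r} "
                    "absent from the code registry"
                )
    window = raw.get("eval_window_days", {"pre": 90, "post": 90})
    params = dict(
        name=raw["name"],
        criteria=criteria,
        policy=raw["policy"],
        default_label=raw.get("default_label", "SCLC"),
        eval_window=(int(window["pre"]), int(window["post"])),
    )
    params.update(overrides)
    return AlgorithmDefinition(**params)


def build_case_finding_algorithm(
    config_path: str | Path | None = None,
    registry: CodeRegistry | None = None,
    **overrides,
) -> AlgorithmDefinition:
    """Build the NSCLC Case-Finding Algorithm (9 SCLC-regimen exclusion
    criteria + the NSCLC-indicative inclusion criteria, exclusion-first)."""
    return _build_from_config("table1_case_finding.yaml", config_path, registry, **overrides)


def build_control_algorithm(
    config_path: str | Path | None = None,
    registry: CodeRegistry | None = None,
    **overrides,
) -> AlgorithmDefinition:
    """Build the control algorithm (every treatment/test row as an inclusion
    criterion, no exclusions)."""
    return _build_from_config("table1_control.yaml", config_path, registry, **overrides)


def classify_patient(
    matches: list, algorithm: AlgorithmDefinition, patient_id: str = ""
) -> ClassificationResult:
    """Turn a full set of criterion matches into a subtype label.

    *matches* must contain exactly one :class:`CriterionMatch` per criterion
    of the algorithm (any order); a mismatch raises :class:`ContractError`.
    """
    by_name = {m.criterion: m for m in matches}
    expected = {c.name for c in algorithm.criteria}
    if set(by_name) != expected or len(by_name) != len(matches):
        raise ContractError(
            "matches must cover the algorithm's criteria exactly "
            f"(got {len(matches)} matches for {len(expected)} criteria)"
        )
    matched_names = [c.name for c in algorithm.criteria if by_name[c.name].matched]

    if algorithm.policy == "exclusion_first":
        for c in algorithm.exclusion_criteria:
            if by_name[c.name].matched:
                return ClassificationResult(
                    patient_id, "SCLC", matched_names, f"sclc_exclusion:{c.name}"
                )
    for c in algorithm.inclusion_criteria:
        if by_name[c.name].matched:
            return ClassificationResult(
                patient_id, "NSCLC", matched_names, f"nsclc_inclusion:{c.name}"
            )
    return ClassificationResult(
        patient_id, algorithm.default_label, matched_names, "default"
    )


def criterion_count_scores(matches: list, algorithm: AlgorithmDefinition) -> dict:
    """Count matched criteria per role.

    This is an extension beyond the dichotomous rule set: the difference
    (inclusion matches minus exclusion matches) gives a crude ordinal score
    usable for ROC experimentation.  It plays no part in classification.
    """
    by_name = {m.criterion: m for m in matches}
    n_inc = sum(1 for c in algorithm.inclusion_criteria if by_name[c.name].matched)
    n_exc = sum(1 for c in algorithm.exclusion_criteria if by_name[c.name].matched)
    return {"n_inclusion": n_inc, "n_exclusion": n_exc, "score": n_inc - n_exc}


def classify_cohort(
    patients: pd.DataFrame,
    claims: pd.DataFrame,
    algorithm: AlgorithmDefinition,
    registry: CodeRegistry | None = None,
) -> list:
    """Classify every patient; one :class:`ClassificationResult` per row of
    *patients*, in order.  Each patient's claims are evaluated inside
    ``[index_date - pre, index_date + post]`` days per the algorithm's
    evaluation window."""
    registry = registry or CodeRegistry.from_yaml()
    pre, post = algorithm.eval_window
    pre_td, post_td = pd.Timedelta(days=pre), pd.Timedelta(days=post)
    claims_by_patient = (
        {pid: g for pid, g in claims.groupby("patient_id", sort=False)}
        if len(claims)
        else {}
    )
    empty = claims.iloc[0:0]
    results = []
    for row in patients.itertuples(index=False):
        pclaims = claims_by_patient.get(row.patient_id, empty)
        index = pd.Timestamp(row.index_date)
        matches = evaluate_all(
            pclaims, algorithm.criteria, registry, index - pre_td, index + post_td
        )
        results.append(classify_patient(matches, algorithm, row.patient_id))
    counts = pd.Series([r.predicted for r in results]).value_counts().to_dict()
    logger.info("classified %d patients with %s: %s", len(results), algorithm.name, counts)
    return results


def results_to_frame(results: list) -> pd.DataFrame:
    """Tabulate classification results (matched criteria ';'-joined)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "predicted": [r.predicted for r in results],
            "matched_criteria": [";".join(r.matched_criteria) for r in results],
            "decisive_rule": [r.decisive_rule for r in results],
        }
    )
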