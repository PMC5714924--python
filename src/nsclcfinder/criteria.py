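"""Declarative treatment/test concepts and criteria, and their matching
against a patient's claims.

A *concept* ("cisplatin", "pet_scan", ...) is a set of (code_system, code)
pairs.  A *criterion* is either a single concept (single agent or procedure)
or a combination regimen: several concepts that must all appear within a
cycle window.  Criteria carry a role — NSCLC-indicative inclusion or
SCLC-indicative exclusion — mirroring the two columns of the published
treatments-and-tests table.

The bundled code lists are placeholders: the licensed GPI/HCPCS/CPT/ICD code
dictionaries behind each concept are user-supplied configuration, and all
correctness guarantees here are at concept level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError

ROLES = ("SCLC_exclusion", "NSCLC_inclusion")

#: Default co-occurrence window for combination regimens: one 21-day
#: chemotherapy cycle.
DEFAULT_COMBO_WINDOW_DAYS = 21


@dataclass(frozen=True)
class CodeList:
    """A clinical concept and the billing codes that identify it."""

    concept: str
    entries: frozenset  # of (code_system, code)

    def __post_init__(self):
        if not self.concept:
            raise ValidationError("concept name must be non-empty")


@dataclass(frozen=True)
class Criterion:
    """A named treatment/test rule.

    ``components`` with length 1 is a single agent or procedure; length >= 2
    is a combination regimen whose components must co-occur within
    ``combo_window_days`` days (ignored for single-component criteria).
    """

    name: str
    role: str
    components: tuple
    combo_window_days: int = DEFAULT_COMBO_WINDOW_DAYS

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"criterion {self.name!r}: unknown role {self.role!r}")
        if not self.components:
            raise ValidationError(f"criterion {self.name!r}: components must be non-empty")
        if self.combo_window_days < 1:
            raise ValidationError(f"criterion {self.name!r}: combo_window_days must be >= 1")


@dataclass
class CriterionMatch:
    """Outcome of evaluating one criterion, with an audit trail.

    ``evidence`` lists (concept, service_date) pairs supporting the match;
    it is empty when ``matched`` is False.
    """

    criterion: str
    matched: bool
    evidence: list = field(default_factory=list)


class CodeRegistry:
    """Registry of concept -> CodeList with a reverse (system, code) index."""

    def __init__(self, codelists: Iterable[CodeList]):
        self._by_concept: dict[str, CodeList] = {}
        for cl in codelists:
            if cl.concept in self._by_concept:
                raise ConfigurationError(f"duplicate concept {cl.concept!r} in registry")
            self._by_concept[cl.concept] = cl
        self._reverse: dict[tuple, list[str]] = {}
        for cl in self._by_concept.values():
            for entry in cl.entries:
                self._reverse.setdefault(entry, []).append(cl.concept)

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "CodeRegistry":
        """Load a registry from a concepts YAML file.

        With no path, the bundled placeholder code lists are loaded.
        """
        if path is None:
            text = resources.files("nsclcfinder.data").joinpath(
                "concepts_placeholder.yaml"
            ).read_text()
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        codelists = [
            CodeList(
                concept=name,
                entries=frozenset((e["system"], str(e["code"])) for e in entries),
            )
            for name, entries in raw["concepts"].items()
        ]
        return cls(codelists)

    def __contains__(self, concept: str) -> bool:
        return concept in self._by_concept

    def __getitem__(self, concept: str) -> CodeList:
        try:
            return self._by_concept[concept]
        except KeyError:
            raise ConfigurationError(
                f"concept {concept!r} is not defined in the code registry"
            ) from None

    @property
    def concepts(self) -> tuple:
        return tuple(self._by_concept)

    def concepts_for(self, code_system: str, code: str) -> list[str]:
        """Concepts whose code list contains (code_system, code)."""
        return self._reverse.get((code_system, code), [])


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def concept_dates(
    claims: pd.DataFrame,
    registry: CodeRegistry,
    window_start,
    window_end,
) -> dict[str, list]:
    """Map each concept to the sorted distinct service dates on which any of
    its codes appears in *claims* within [window_start, window_end]."""
    window_start = pd.Timestamp(window_start)
    window_end = pd.Timestamp(window_end)
    out: dict[str, set] = {}
    for row in claims.itertuples(index=False):
        d = pd.Timestamp(row.service_date)
        if not (window_start <= d <= window_end):
            continue
        for concept in registry.concepts_for(row.code_system, row.code):
            out.setdefault(concept, set()).add(d)
    return {c: sorted(ds) for c, ds in out.items()}


def match_concept(
    claims: pd.DataFrame,
    registry: CodeRegistry,
    concept: str,
    window_start,
    window_end,
) -> list:
    """Distinct service dates on which *concept* appears inside the window.

    Raises :class:`ConfigurationError` if the concept is not registered.
    """
    if pd.Timestamp(window_start) > pd.Timestamp(window_end):
        raise ValueError("window_start must not be after window_end")
    registry[concept]  # raises on unknown concept
    codes = registry[concept].entries
    dates = {
        pd.Timestamp(row.service_date)
        for row in claims.itertuples(index=False)
        if (row.code_system, row.code) in codes
        and pd.Timestamp(window_start) <= pd.Timestamp(row.service_date) <= pd.Timestamp(window_end)
    }
    return sorted(dates)


def _detect_from_dates(
    dates_by_concept: Mapping[str, list], criterion: Criterion
) -> CriterionMatch:
    """Criterion evaluation over precomputed per-concept date lists."""
    components = criterion.components
    if len(components) == 1:
        dates = dates_by_concept.get(components[0], [])
        if dates:
            return CriterionMatch(criterion.name, True, [(components[0], dates[0])])
        return CriterionMatch(criterion.name, False)

    per_component = [dates_by_concept.get(c, []) for c in components]
    if any(not d for d in per_component):
        return CriterionMatch(criterion.name, False)
    window = pd.Timedelta(days=criterion.combo_window_days - 1)
    # An anchor can be restricted to observed component dates: if all
    # components fit in some [a, a + w], they also fit in the window anchored
    # at their earliest member.
    anchors = sorted({d for dates in per_component for d in dates})
    for anchor in anchors:
        evidence = []
        for concept, dates in zip(components, per_component):
            hit = next((d for d in dates if anchor <= d <= anchor + window), None)
            if hit is None:
                break
            evidence.append((concept, hit))
        else:
            return CriterionMatch(criterion.name, True, evidence)
    return CriterionMatch(criterion.name, False)


def detect_criterion(
    claims: pd.DataFrame,
    criterion: Criterion,
    registry: CodeRegistry,
    window_start,
    window_end,
) -> CriterionMatch:
    """Evaluate one criterion against a patient's claims.

    Single-component criteria match when the concept appears anywhere inside
    the evaluation window.  Combination regimens match when some anchor date
    exists such that every component appears within
    ``[anchor, anchor + combo_window_days - 1]``, all inside the window.
    """
    for concept in criterion.components:
        registry[concept]  # unknown concept -> ConfigurationError
    dates = concept_dates(claims, registry, window_start, window_end)
    relevant = {c: dates.get(c, []) for c in criterion.components}
    return _detect_from_dates(relevant, criterion)


def evaluate_all(
    claims: pd.DataFrame,
    criteria: Iterable[Criterion],
    registry: CodeRegistry,
    window_start,
    window_end,
) -> list:
    """Evaluate every criterion; one CriterionMatch per criterion, in order."""
    criteria = list(criteria)
    for criterion in criteria:
        for concept in criterion.components:
            registry[concept]
    dates = concept_dates(claims, registry, window_start, window_end)
    return [_detect_from_dates(dates, c) for c in criteria]


def load_criteria_yaml(path_or_text) -> dict:
    """Parse a criteria YAML file into its raw dict (used by the algorithm
    builders; exposed for custom algorithm definitions)."""
    text = str(path_or_text)
    if "\n" not in text and Path(text).exists():
        text = Path(text).read_text()
    return yaml.safe_load(text)
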