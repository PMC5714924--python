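"""Shared fixtures: the bundled registry/algorithms and small claim builders."""

from __future__ import annotations

import pandas as pd
import pytest

from nsclcfinder.algorithms import build_case_finding_algorithm, build_control_algorithm
from nsclcfinder.criteria import CodeRegistry


@pytest.fixture(scope="session")
def registry() -> CodeRegistry:
    return CodeRegistry.from_yaml()


@pytest.fixture(scope="session")
def case_finding(registry):
    return build_case_finding_algorithm(registry=registry)


@pytest.fixture(scope="session")
def control(registry):
    return build_control_algorithm(registry=registry)


def claims_frame(rows) -> pd.DataFrame:
    """Build a claims DataFrame from (patient_id, date, code_system, code)."""
    df = pd.DataFrame(rows, columns=["patient_id", "service_date", "code_system", "code"])
    df["service_date"] = pd.to_datetime(df["service_date"])
    return df


@pytest.fixture()
def concept_claims(registry):
    """Factory: claims for one patient from (concept, date) pairs, using the
    first registered code of each concept."""

    def _make(pairs, patient_id="P1") -> pd.DataFrame:
        rows = []
        for concept, date in pairs:
            system, code = sorted(registry[concept].entries)[0]
            rows.append((patient_id, date, system, code))
        return claims_frame(rows)

    return _make
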