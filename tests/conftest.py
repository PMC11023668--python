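import numpy as np
import pandas as pd
import pytest

from ehrpgx import (
    GenerativeParams,
    RxBehavior,
    ScenarioConfig,
    VariantSpec,
    VisitSchedule,
    default_code_map,
)


@pytest.fixture(scope="session")
def code_map():
    return default_code_map()


@pytest.fixture
def lenient():
    return ScenarioConfig(mode="lenient", measure_mode="single", min_drug_group_size=1, min_cohort_size=1)


@pytest.fixture
def stringent():
    return ScenarioConfig(mode="stringent", measure_mode="single", min_drug_group_size=1, min_cohort_size=1)


def measures_frame(rows):
    """rows: (person_id, date, value) triples for LDL in mmol/L."""
    return pd.DataFrame(
        [
            {"person_id": p, "date": d, "biomarker": "LDL", "value": v, "unit": "mmol_L", "source": "ehr"}
            for p, d, v in rows
        ]
    )


def rx_frame(rows):
    """rows: (person_id, date, code, description) tuples."""
    return pd.DataFrame(
        [
            {"person_id": p, "date": d, "code": c, "description": desc, "quantity": 28}
            for p, d, c, desc in rows
        ]
    )


@pytest.fixture(scope="session")
def small_ehr():
    """A small treated population with one baseline-and-PGx variant."""
    from ehrpgx import simulate_ehr

    params = GenerativeParams(
        variants=[VariantSpec("v0", 0.3, beta0=0.3, gammaD=0.2), VariantSpec("v1", 0.2)],
        betaD=-1.0,
    )
    return simulate_ehr(400, params, RxBehavior(), VisitSchedule(), seed=11)
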