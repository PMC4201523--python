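import numpy as np
import pandas as pd
import pytest

from rrdcua import (BootstrapSettings, Cohort, EconParams, GeneratorParams,
                    LifeTable, PatientRecord, generate_cohort)


def make_patient(patient_id="p1", **overrides) -> PatientRecord:
    base = dict(
        patient_id=patient_id,
        age=78,
        sex="male",
        education_years=9.0,
        surgery_type="vitrectomy",
        bilateral=False,
        macula_off=True,
        quadrants_detached=3,
        symptom_duration_weeks=5.0,
        bcva_pre_logmar=1.1,
        bcva_3m_logmar=0.7,
        bcva_1y_logmar=0.5,
        utility_pre=0.77,
        utility_1y=0.84,
        cost_total_cny=13000.0,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def five_row_cohort() -> Cohort:
    """Small hand-built cohort spanning both age strata and surgery types."""
    return Cohort([
        make_patient("a", age=72, sex="male", surgery_type="scleral_buckle",
                     utility_pre=0.70, utility_1y=0.80, cost_total_cny=11000.0,
                     bcva_pre_logmar=1.3, bcva_3m_logmar=0.9, bcva_1y_logmar=0.6),
        make_patient("b", age=75, sex="female", utility_pre=0.85, utility_1y=0.90,
                     cost_total_cny=14500.0, bilateral=True),
        make_patient("c", age=78, sex="male", utility_pre=0.77, utility_1y=0.84,
                     cost_total_cny=12992.0),
        make_patient("d", age=82, sex="female", utility_pre=0.80, utility_1y=0.83,
                     cost_total_cny=9800.0, surgery_type="scleral_buckle",
                     quadrants_detached=2),
        make_patient("e", age=85, sex="male", utility_pre=0.65, utility_1y=0.72,
                     cost_total_cny=16750.0, macula_off=False),
    ])


@pytest.fixture
def life_table() -> LifeTable:
    rows = [(70, "male", 13.0), (80, "male", 7.5), (90, "male", 4.0),
            (70, "female", 15.0), (80, "female", 9.0), (90, "female", 5.0)]
    return LifeTable(pd.DataFrame(rows, columns=["age", "sex", "life_expectancy_years"]))


@pytest.fixture
def params() -> EconParams:
    return EconParams()


@pytest.fixture
def settings() -> BootstrapSettings:
    return BootstrapSettings(replications=1000, seed=7)


@pytest.fixture(scope="session")
def synthetic_cohort_98() -> Cohort:
    return generate_cohort(GeneratorParams(n=98, seed=42))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
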