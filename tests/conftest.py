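import numpy as np
import pytest

from losnet.records import DRGReference, HospitalizationRecord
from losnet.simulate import default_department_config, generate_cohort


def make_record(i=0, **overrides) -> HospitalizationRecord:
    base = dict(
        record_id=f"R{i:04d}",
        unit="cardiology",
        sex=1,
        age_class="41-65",
        cancer=0,
        admission_type="planned",
        time_slot="morning",
        weekday="Mon",
        diagnosis_code="4280",
        diagnosis_group="heart failure",
        drg_code="127",
        los_days=6.0,
        discharge_mode="home",
        transfer=0,
        year=2018,
    )
    base.update(overrides)
    return HospitalizationRecord(**base)


@pytest.fixture
def drg_ref_small():
    return {
        "127": DRGReference("127", 5.764, 12.0, 3000.0),
        "089": DRGReference("089", 9.219, 20.0, 4000.0),
    }


@pytest.fixture(scope="session")
def default_cohort():
    """Department-calibrated cohort, 10k records, fixed seed."""
    cfg = default_department_config(n_records=10_000, seed=20180101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def dominant_cohort():
    """Cohort with one dominant planted effect (cancer, +2.0 log-days)."""
    cfg = default_department_config(n_records=6_000, seed=77).replace(
        effects={"cancer": 2.0}, sigma=0.3)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
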