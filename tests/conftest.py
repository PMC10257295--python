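import numpy as np
import pytest

from densityjm import defaults
from densityjm.cohort import SimulationConfig, simulate_cohort
from densityjm.model import LongitudinalParams, SubjectRecord
from densityjm.splines import BaselineHazardSpec, SplineSpec


@pytest.fixture(scope="session")
def spline_spec() -> SplineSpec:
    return SplineSpec()


@pytest.fixture(scope="session")
def baseline_spec() -> BaselineHazardSpec:
    return BaselineHazardSpec()


@pytest.fixture(scope="session")
def long_params() -> LongitudinalParams:
    return defaults.longitudinal_params()


@pytest.fixture
def subject() -> SubjectRecord:
    return SubjectRecord(
        id=1, entry_time=12.0, exit_time=20.0, event=1,
        bmi=24.0, mht="former", mp="post", fh="yes",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with an elevated event rate (session-shared)."""
    sp = defaults.survival_params(assoc="current_value", baseline_intercept=-5.0)
    cfg = SimulationConfig(n_subjects=120, seed=77, surv_params=sp)
    subjects, longitudinal, truth = simulate_cohort(cfg)
    return subjects, longitudinal, truth
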