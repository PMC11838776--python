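import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ptspo import CohortConfig, TriExpFit, generate_cohort
from ptspo.schedule import PRESET_SCHEDULES
from ptspo.workflows import design_from_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pbr28_schedule():
    return PRESET_SCHEDULES["pbr28_90min"]


@pytest.fixture(scope="session")
def blood_fit():
    """Representative input model (kBq/mL for ~330 MBq in a 75 kg subject)."""
    return TriExpFit(np.array([44.0, 15.4, 3.5]), np.array([3.0, 0.35, 0.02]),
                     peak_time=0.75)


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject, 3-dataset cohort at default study conditions."""
    return generate_cohort(CohortConfig(seed=7, n_subjects=12))


@pytest.fixture(scope="session")
def small_design(small_cohort):
    design, spec = design_from_cohort(small_cohort)
    return design, spec
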