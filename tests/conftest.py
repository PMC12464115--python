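import numpy as np
import pytest

from itpav.cohort import CohortConfig, generate_cohort
from itpav.models import MODELS, ModelParams
from itpav.task import generate_schedule


@pytest.fixture(scope="session")
def schedule200():
    """A full-length task schedule (4 x 50 trials, max run 2, 80% valid)."""
    return generate_schedule(50, 2, 0.8, seed=101)


@pytest.fixture(scope="session")
def schedule3():
    """A 3-trial schedule for exhaustive likelihood enumeration."""
    sched = generate_schedule(1, 2, 0.8, seed=5)
    sched.trials = sched.trials[:3]
    return sched


@pytest.fixture(scope="session")
def m3_params():
    return ModelParams(alpha=0.25, tau=6.0, xi=0.15, b=0.2, pi=0.4)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant synthetic cohort shared across tests."""
    cfg = CohortConfig(n_participants=12)
    return generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def rich_params():
    """A parameter setting in which every component of M5 is active."""
    return ModelParams(alpha=0.3, tau=4.0, xi=0.2, b=0.4, pi=0.6,
                       alpha0=0.5, alpha1=0.15)
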