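import numpy as np
import pytest

from hierpet.cohort import CohortConfig, simulate_cohort
from hierpet.kinetic import ArterialInput, FrameSchedule


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def exp_input():
    """Piecewise-linear input sampling exp(-0.1 t), whole plasma 1.3x."""
    t = np.unique(np.concatenate([
        np.linspace(0.0, 3.0, 60), np.linspace(3.0, 20.0, 60),
        np.linspace(20.0, 110.0, 80)]))
    cp = np.exp(-0.1 * t)
    return ArterialInput(t, cp, 1.3 * cp, fP=0.08)


@pytest.fixture(scope="session")
def tiny_study():
    """Noiseless 2-subject x 2-region study for exact-recovery tests."""
    cfg = CohortConfig(group_sizes={"HV": 1, "NRM": 1, "AE": 0},
                       regions=("DLPFC", "RN"), include_reference=True)
    return simulate_cohort(cfg, seed=42, noise=False)


@pytest.fixture(scope="session")
def small_noisy_study():
    """Small noisy cohort shared across hierarchical-model tests."""
    cfg = CohortConfig(group_sizes={"HV": 4, "NRM": 3, "AE": 3},
                       regions=("DLPFC", "HIP", "RN"),
                       include_reference=True)
    return simulate_cohort(cfg, seed=7)
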