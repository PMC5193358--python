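import numpy as np
import pytest

import gaitcost as gc


@pytest.fixture(scope="session")
def male_catalog():
    return gc.default_catalog("M")


@pytest.fixture(scope="session")
def female_catalog():
    return gc.default_catalog("F")


@pytest.fixture(scope="session")
def published():
    return gc.published_weights()


@pytest.fixture(scope="session")
def male_mean_subject():
    """Estimation-group male mean: 1.83 m, 87.9 kg, 31 yr, 212.4 N*m."""
    return gc.SubjectProfile(
        id="male-mean", sex="M", mass_kg=87.9, height_m=1.83, age_yr=31.0,
        knee_max_torque_Nm=212.4, bmr_W=85.0, vo2max_W=1100.0,
    )


@pytest.fixture(scope="session")
def female_mean_subject():
    return gc.SubjectProfile(
        id="female-mean", sex="F", mass_kg=57.1, height_m=1.62, age_yr=32.0,
        knee_max_torque_Nm=107.6, bmr_W=70.0, vo2max_W=750.0,
    )


def single_dof_trial(tau=10.0, qd=1.0, v=1.3, n=50, duration=1.0, qcc=None):
    """Constant-input one-DOF trial for forced-arithmetic checks."""
    t = np.linspace(0.0, duration, n)
    ones = np.ones((n, 1))
    return gc.GaitTrial(
        t=t, q=np.zeros((n, 1)), qd=qd * ones, tau=tau * ones,
        v=v * np.ones(n), dof_ids=("j0",),
        qcc=None if qcc is None else qcc * ones,
    )


@pytest.fixture
def one_dof_trial():
    return single_dof_trial()
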