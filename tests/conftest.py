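import numpy as np
import pytest

from elmfit.simulate import (
    TrialDesign,
    constrain_truth,
    fixture_kamprath_params,
    generate,
)

#: published invariant values for the three-soil corn study
DELTA_B = 0.660
N_CM_GRAIN = 14.0
N_CM_TOTAL = 9.18


@pytest.fixture(scope="session")
def kamprath_truth():
    """Per-site parameters as published for the three NC soils."""
    return fixture_kamprath_params()


@pytest.fixture(scope="session")
def mode_iii_truth(kamprath_truth):
    """The Kamprath parameters projected onto the invariant structure
    (common delta_b and N_cm), so the truth satisfies Mode III exactly."""
    return constrain_truth(kamprath_truth, DELTA_B, N_CM_GRAIN, N_CM_TOTAL)


@pytest.fixture(scope="session")
def common_db_truth(kamprath_truth):
    """Common-delta_b (Mode II) truth: the null of the invariance test."""
    return constrain_truth(kamprath_truth, DELTA_B)


@pytest.fixture(scope="session")
def noiseless_series(mode_iii_truth):
    series, _ = generate(TrialDesign(noise_cv=0.0), mode_iii_truth)
    return series


@pytest.fixture()
def noisy_series(mode_iii_truth):
    series, _ = generate(TrialDesign(noise_cv=0.02, seed=1234), mode_iii_truth)
    return series


@pytest.fixture(scope="session")
def dothan(kamprath_truth):
    return kamprath_truth.by_id()["Dothan"]


@pytest.fixture(scope="session")
def portsmouth(kamprath_truth):
    return kamprath_truth.by_id()["Portsmouth"]
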