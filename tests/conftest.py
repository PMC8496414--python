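import numpy as np
import pytest

import vfprog as vf


@pytest.fixture(scope="session")
def grid():
    return vf.load_grid()


@pytest.fixture(scope="session")
def var_model():
    return vf.default_variability_model()


@pytest.fixture(scope="session")
def small_cohort():
    """Six mixed eyes, 10 visits, default clinic-like parameters."""
    return vf.generate_cohort(vf.CohortSpec(n_eyes=6, seed=42))


@pytest.fixture(scope="session")
def one_eye(small_cohort):
    return small_cohort[0]


def make_series(values, times=None, eye_id="eye"):
    """Series from a (n_tests, 54) array (helper used across test modules)."""
    values = np.asarray(values)
    if times is None:
        times = np.arange(values.shape[0], dtype=float)
    tests = [vf.VFTest(float(t), v) for t, v in zip(times, values)]
    return vf.VFSeries(eye_id, tests)


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced MCMC settings for unit tests."""
    return {"warmup": 250, "draws": 400, "max_doublings": 1}
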