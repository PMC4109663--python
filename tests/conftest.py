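import numpy as np
import pytest

from bayeserp.simulate import DEFAULT_NOISE, generate_study, make_erp_template


@pytest.fixture(scope="session")
def template():
    return make_erp_template(peak_latency_ms=450.0, peak_amplitude=10.0, fwhm_ms=250.0)


@pytest.fixture(scope="session")
def noise():
    return DEFAULT_NOISE


@pytest.fixture(scope="session")
def small_study():
    """Tiny study (2 calibration sessions, 1 session/day) for structural tests."""
    return generate_study(
        n_subjects=1, sessions_per_day=1, n_calibration_sessions=2,
        snr_db_range=(6.0, 6.0), seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
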