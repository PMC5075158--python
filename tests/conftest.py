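import numpy as np
import pytest

from hadsim import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def default_spec():
    """Generator calibrated to the published descriptives (cached)."""
    return default_cohort_spec()


@pytest.fixture(scope="session")
def big_cohort(default_spec):
    """Large cohort for checking calibration residuals at low Monte-Carlo noise."""
    return generate_cohort(default_spec, rng=20_221_01, n=100_000)


@pytest.fixture(scope="session")
def source_cohort(default_spec):
    """Synthetic stand-in for a complete source dataset to bootstrap from."""
    return generate_cohort(default_spec, rng=7, n=1385)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
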