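import numpy as np
import pytest

import leafmetal as lm


@pytest.fixture(scope="session")
def default_cohort():
    """Default 22-site cohort, fixed seed."""
    return lm.generate_cohort(lm.CohortConfig(seed=123))


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for marginal/correlation calibration checks."""
    return lm.generate_cohort(lm.CohortConfig(n_sites=10_000, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_spectra(rng):
    """Random 5x20 spectra on a uniform grid, values in (0, 1)."""
    wl = 400.0 + 10.0 * np.arange(20)
    refl = 0.2 + 0.6 * rng.random((5, 20))
    ids = np.array([f"S{i:02d}" for i in range(1, 6)])
    return lm.SpectraSet(site_ids=ids, wavelengths_nm=wl, reflectance=refl)
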