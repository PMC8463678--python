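import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import isodendro as iso

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def series_with_stats(mean: float, sd: float, n: int = 2,
                      start_year: int = 2000) -> pd.Series:
    """Annual series whose sample mean and sample SD are exactly as given."""
    base = np.resize([-1.0, 1.0], n)
    base -= base.mean()
    base /= base.std(ddof=1)
    return pd.Series(mean + sd * base, index=np.arange(start_year, start_year + n))


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic scenario: 42 trees, full study-period span."""
    return iso.generate_dataset(seed=42)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """All stochastic terms off, no Suess imprint: pure affine climate map."""
    return iso.generate_dataset(
        year_range=(1800, 2009), n_trees=8,
        tree_sd=0.0, noise_sd=0.0, juvenile_amplitude=0.0,
        with_suess=False, volcanic_cooling=0.0, seed=5,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Short, cheap scenario for I/O and pipeline tests."""
    return iso.generate_dataset(year_range=(1900, 2009), n_trees=10, seed=11)
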