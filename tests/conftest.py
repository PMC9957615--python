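import pytest
from hypothesis import settings as _hsettings

from pastoral.landscape import LandscapeConfig

_hsettings.register_profile("default", derandomize=True, deadline=None)
_hsettings.load_profile("default")
from pastoral.simulate import build_setup, run_query
from pastoral.components import FULL_SYSTEM_QUERY


@pytest.fixture(scope="session")
def small_setup():
    """A 10x10 synthetic landscape with 60 days of climate."""
    cfg = LandscapeConfig(seed=1, ncols=10, nrows=10, n_vegetation_types=5,
                          n_livestock_groups=4, animals_per_group=5)
    return build_setup(cfg, n_days=60)


@pytest.fixture(scope="session")
def small_run(small_setup):
    """A full-system run on the small landscape (store, dataflow)."""
    return run_query(small_setup, list(FULL_SYSTEM_QUERY))


@pytest.fixture(scope="session")
def tiny_setup():
    """A 5x5 landscape with 30 days of climate, for oracle comparison."""
    cfg = LandscapeConfig(seed=7, ncols=5, nrows=5, n_vegetation_types=3,
                          elevation_max=500.0,
                          n_livestock_groups=2, animals_per_group=3)
    return build_setup(cfg, n_days=30)
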