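import numpy as np
import pytest

from dielco2.carbsys import SeawaterState
from dielco2.synthgen import build_grid, load_default_config


@pytest.fixture(scope="session")
def gen_config():
    return load_default_config()


@pytest.fixture(scope="session")
def small_grid(gen_config):
    return build_grid(12, seed=777, config=gen_config)


@pytest.fixture
def example_state():
    """Temperate open-ocean surface state used across solver tests."""
    return SeawaterState(temperature=18.0, salinity=35.0, dic=2050.0,
                         alkalinity=2300.0, phosphate=0.5, silicate=5.0)


@pytest.fixture(scope="session")
def state_sample():
    """Latin-hypercube style sample of valid surface states (shuffled grids)."""
    rng = np.random.default_rng(42)
    n = 1000
    def lhs(lo, hi):
        strata = (np.arange(n) + rng.random(n)) / n
        return lo + (hi - lo) * rng.permutation(strata)

    t = lhs(-1.5, 32.0)
    s = lhs(30.0, 38.0)
    alk = lhs(2150.0, 2450.0)
    # DIC between ~88% and ~98% of alkalinity spans pCO2 ~150-1500 µatm
    dic = alk * lhs(0.88, 0.98)
    po4 = lhs(0.0, 2.0)
    si = lhs(0.0, 60.0)
    return SeawaterState(temperature=t, salinity=s, dic=dic, alkalinity=alk,
                         phosphate=po4, silicate=si)
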