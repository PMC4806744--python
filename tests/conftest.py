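import numpy as np
import pytest

from bearsalmon import synthetic as syn
from bearsalmon.diet import Fractionation, SourceSpec


@pytest.fixture(scope="session")
def sim_config():
    return syn.SimConfig(seed=7)


@pytest.fixture(scope="session")
def small_config():
    """A reduced study for fast end-to-end runs."""
    return syn.SimConfig(
        seed=11, n_streams=12, n_years=13,
        n_bears={("grizzly", "male"): 20, ("grizzly", "female"): 6,
                 ("black", "male"): 22, ("black", "female"): 5})


@pytest.fixture(scope="session")
def sources():
    return SourceSpec.default_synthetic()


@pytest.fixture(scope="session")
def fractionation():
    return Fractionation.default_synthetic()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def exact_sources():
    """Zero source/fractionation SD: only the residual term remains."""
    zero = {(s, j): 0.0 for s in ("salmon", "plant") for j in ("d13C", "d15N")}
    src = SourceSpec(
        mean={("salmon", "d13C"): -19.0, ("salmon", "d15N"): 14.0,
              ("plant", "d13C"): -27.0, ("plant", "d15N"): -1.0},
        sd=zero)
    frac = Fractionation(
        mean={("salmon", "d13C"): 2.0, ("salmon", "d15N"): 3.0,
              ("plant", "d13C"): 2.0, ("plant", "d15N"): 3.0},
        sd=zero, residual_sd={"d13C": 0.5, "d15N": 0.5})
    return src, frac
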