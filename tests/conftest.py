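import numpy as np
import pytest
from hypothesis import settings

from fibriltip import get_preset
from fibriltip.model import RateSet

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig3():
    return get_preset("fig3_abeta_fit")


@pytest.fixture(scope="session")
def fig7():
    return get_preset("fig7_stop_go")


def random_regime1_rates(rng: np.random.Generator) -> tuple[RateSet, float]:
    """A random rate set plus a concentration strictly inside regime 1."""
    rates = RateSet(
        k_p_cc=float(rng.uniform(0.5, 5.0)),
        k_d_cc=float(rng.uniform(10.0, 200.0)),
        k_p_bc=float(rng.uniform(0.1, 2.0)),
        k_d_bc=float(rng.uniform(1.0, 50.0)),
        s_cb=float(rng.uniform(1.0, 50.0)),
    )
    css = (rates.k_d_cc + rates.s_cb) / rates.k_p_cc
    conc = float(rng.uniform(0.2, 0.85)) * css
    return rates, conc
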