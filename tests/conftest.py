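import numpy as np
import pytest

from healthprod.ebm import EBMParams
from healthprod.synthetic import fixture_table3
from healthprod.weights import china_contiguity


@pytest.fixture(scope="session")
def china_w():
    return china_contiguity()


@pytest.fixture(scope="session")
def table3():
    return fixture_table3()


def random_instance(rng, n=8, m=2, s=1, q=1, spread=0.4):
    """Lognormal cross-section (x, y, u) for DEA property tests."""
    x = np.exp(rng.normal(0.0, spread, (m, n)))
    y = np.exp(rng.normal(0.0, spread, (s, n)))
    u = np.exp(rng.normal(0.0, spread, (q, n)))
    return x, y, u


def uniform_params(m=2, s=1, q=1, eps_in=0.0, eps_out=0.0, rts="CRS"):
    return EBMParams(
        eps_in, eps_out,
        np.full(m, 1.0 / m),
        np.full(s, 1.0 / (s + q)),
        np.full(q, 1.0 / (s + q)),
        rts,
    )
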