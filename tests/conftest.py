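import math

import numpy as np
import pytest

from riisvalve import assemble_valve, generate_fixture
from riisvalve.params import LeafletParameters


def random_leaflet(rng: np.random.Generator) -> LeafletParameters:
    """A random admissible leaflet parameter set spanning the model's ranges."""
    l_ro = rng.uniform(10.0, 17.0)
    l_a = rng.uniform(math.radians(35.0), math.radians(80.0))
    l_h = rng.uniform(7.0, 13.0)
    l_ri = rng.uniform(0.12, 0.75) * l_ro
    b_h = rng.uniform(0.3, 0.7) * l_h
    b_ro = rng.uniform(0.8, 1.0) * l_ro
    b_ri = rng.uniform(0.3, 0.999) * min(b_ro, l_ri + 2.0)
    return LeafletParameters(
        l_ro=l_ro, l_ri=l_ri, l_a=l_a,
        l_p=rng.uniform(1.5, 6.0), l_h=l_h,
        r_r=rng.uniform(9.0, 15.0),
        b_ro=b_ro, b_ri=b_ri,
        b_a=rng.uniform(math.radians(35.0), math.radians(80.0)),
        b_p=rng.uniform(1.5, 6.0), b_h=b_h,
        theta=rng.uniform(0.0, 2.0 * math.pi),
        t0=rng.uniform(0.05, 0.95), t3=rng.uniform(0.05, 0.95))


@pytest.fixture(scope="session")
def severe_params():
    return generate_fixture("severe", seed=42)


@pytest.fixture(scope="session")
def severe_valve(severe_params):
    return assemble_valve(severe_params)


@pytest.fixture(scope="session")
def moderate_valve():
    return assemble_valve(generate_fixture("moderate", seed=42))
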