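import numpy as np
import pytest

from scareulm import graph as G
from scareulm.pipeline import diamond_graph, synthetic_u_track


@pytest.fixture
def diamond():
    """Smallest closure: artery -> arteriole -> two parallel capillaries
    -> venule -> vein."""
    return diamond_graph()


@pytest.fixture
def solved_diamond(diamond):
    return G.solve_hemodynamics(diamond, inlet_pressure_pa=1000.0,
                                outlet_pressure_pa=0.0)


@pytest.fixture
def small_network():
    cfg = G.GraphConfig(n_capillaries=12, seed=11)
    vg = G.generate_graph(cfg)
    return G.solve_hemodynamics(vg)


@pytest.fixture
def u_track():
    return synthetic_u_track(dwell_s=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
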