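import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import delayprop as dp

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sim():
    return dp.SimParams(T=30, D_max=9)


def random_net(
    rng,
    sim,
    n_in=5,
    n_hidden=4,
    n_out=3,
    flavor_in="synaptic",
    flavor_rec="none",
    recurrent=False,
    density=1.0,
    spike_rate=0.25,
    weight_scale=1.0,
):
    """Random network plus a random raster/label for gradient tests."""
    params = dp.init_network(
        n_in,
        n_hidden,
        n_out,
        sim,
        flavor_in=flavor_in,
        flavor_rec=flavor_rec,
        recurrent=recurrent,
        density=density,
        rng=rng,
    )
    params.W_in *= weight_scale
    if params.W_rec is not None:
        params.W_rec *= weight_scale
    spikes = (rng.random((sim.T, n_in)) < spike_rate).astype(np.uint8)
    raster = dp.SpikeRaster(spikes, dt=sim.dt)
    label = int(rng.integers(n_out))
    return params, raster, label


@pytest.fixture
def net_factory(rng, small_sim):
    def make(**kw):
        sim = kw.pop("sim", small_sim)
        return (sim,) + random_net(rng, sim, **kw)

    return make
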