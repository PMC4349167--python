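import numpy as np
import pytest

from spikephase.engine import SpikeRaster, TrialConfig
from spikephase.network import NetworkConfig, build_network


@pytest.fixture(scope="session")
def small_net():
    """A 100-neuron zero-weight network: stimulated spikes never propagate."""
    return build_network(NetworkConfig(N=100, N_i=20, p=0.05,
                                       w_e=0.0, w_i=0.0, seed=42))


@pytest.fixture(scope="session")
def coupled_net():
    """A small strongly excitatory network (activity propagates past t=0)."""
    return build_network(NetworkConfig(N=100, N_i=20, p=0.1,
                                       w_e=100.0, w_i=0.0, seed=7))


@pytest.fixture
def short_cfg():
    return TrialConfig(T=256, stim_seed=11)


def raster_from_events(times, neurons, T=1024, N=100, s=0):
    return SpikeRaster(times=np.asarray(times, dtype=np.int64),
                       neurons=np.asarray(neurons, dtype=np.int64),
                       T=T, s=s, inhibitory=np.zeros(N, dtype=bool))
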