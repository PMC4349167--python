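"""Impulse trials: protocol construction, forced firing at t=0, propagation,
causality in uncoupled networks, determinism, raster IO, and agreement of
the vectorized network step with the scalar single-neuron reference."""

import numpy as np
import pytest

from spikephase.engine import (SpikeRaster, StimulusProtocol, TrialConfig,
                               make_protocol, read_raster, run_protocol,
                               run_trial, write_raster)
from spikephase.network import NetworkConfig, build_network
from spikephase.neuron import (NeuronState, initial_state,
                               regular_spiking_params, step)


class TestProtocol:
    def test_default_ladder_matches_published_sequence(self):
        proto = make_protocol(256)
        assert tuple(proto) == (0, 1, 2, 4, 8, 16, 32, 64, 128, 256)
        assert len(proto) == 10

    def test_minimal_ladder(self):
        assert tuple(make_protocol(1)) == (0, 1)

    def test_one_stop_spacing(self):
        mags = tuple(make_protocol(128))
        assert all(b == 2 * a for a, b in zip(mags[1:], mags[2:]))

    @pytest.mark.parametrize("bad", [0, 3, 6, 100, -8])
    def test_non_power_of_two_rejected(self, bad):
        with pytest.raises(ValueError):
            make_protocol(bad)

    def test_malformed_protocol_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol((1, 2, 4))      # missing resting stimulus
        with pytest.raises(ValueError):
            StimulusProtocol((0, 1, 3))      # not one-stop spaced


class TestRunTrial:
    def test_no_stimulus_means_no_activity(self, small_net, short_cfg):
        raster = run_trial(small_net, 0, short_cfg)
        assert raster.n_spikes == 0

    def test_zero_weights_exactly_s_spikes_at_t0(self, small_net, short_cfg):
        raster = run_trial(small_net, 5, short_cfg)
        assert raster.n_spikes == 5
        assert np.all(raster.times == 0)
        # all stimulated neurons are excitatory
        assert not raster.inhibitory[raster.neurons].any()

    def test_causality_no_spike_after_t0_without_coupling(self, small_net):
        raster = run_trial(small_net, 50, TrialConfig(T=1024, stim_seed=3))
        assert raster.times.max() == 0

    def test_strong_coupling_propagates(self, coupled_net, short_cfg):
        raster = run_trial(coupled_net, 20, short_cfg)
        assert np.any(raster.times > 0)

    def test_at_most_one_spike_per_neuron_per_bin(self, coupled_net, short_cfg):
        raster = run_trial(coupled_net, 20, short_cfg)
        pairs = set(zip(raster.times.tolist(), raster.neurons.tolist()))
        assert len(pairs) == raster.n_spikes

    def test_determinism(self, coupled_net, short_cfg):
        a = run_trial(coupled_net, 16, short_cfg)
        b = run_trial(coupled_net, 16, short_cfg)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.neurons, b.neurons)

    def test_stimulus_exceeding_excitatory_count_rejected(self, small_net):
        with pytest.raises(ValueError):
            run_trial(small_net, small_net.n_excitatory + 1)

    def test_matches_scalar_reference_for_single_postsynaptic_drive(self):
        """A 2-neuron chain: neuron 0 is stimulated, neuron 1 receives one
        current pulse of w_e at t=1; the network integrator must reproduce
        the scalar step() trajectory for neuron 1 bit-for-bit."""
        cfg = NetworkConfig(N=2, N_i=1, p=0.0, w_e=50.0, w_i=0.0, seed=0)
        net = build_network(cfg)
        # hand-wire the single edge 0 -> 1 (excitatory -> inhibitory or not,
        # weight is the presynaptic type's)
        import scipy.sparse as sp
        exc = int(net.excitatory_indices[0])
        other = 1 - exc
        w = np.zeros((2, 2))
        w[exc, other] = 50.0
        net.weights = sp.csr_matrix(w)
        raster = run_trial(net, 1, TrialConfig(T=64, stim_seed=0))
        # scalar oracle for the postsynaptic neuron
        params = (net.params_inhibitory if net.inhibitory[other]
                  else net.params_excitatory)
        state = initial_state()
        oracle_spikes = []
        for t in range(1, 64):
            I = 50.0 if t == 1 else 0.0
            state, fired = step(state, params, I)
            if fired:
                oracle_spikes.append(t)
        got = sorted(raster.times[raster.neurons == other].tolist())
        assert got == oracle_spikes


class TestRunProtocol:
    def test_one_raster_per_stimulus(self, small_net, short_cfg):
        proto = make_protocol(16)
        rasters = run_protocol(small_net, proto, short_cfg)
        assert len(rasters) == len(proto)

    def test_trials_are_independent_spike_counts_equal_s(self, small_net, short_cfg):
        proto = make_protocol(64)
        rasters = run_protocol(small_net, proto, short_cfg)
        assert [r.n_spikes for r in rasters] == list(proto)

    def test_protocol_beyond_population_rejected(self, small_net, short_cfg):
        with pytest.raises(ValueError):
            run_protocol(small_net, make_protocol(256), short_cfg)


class TestRasterIO:
    def test_round_trip(self, coupled_net, short_cfg, tmp_path):
        raster = run_trial(coupled_net, 8, short_cfg)
        path = tmp_path / "raster.txt"
        write_raster(raster, path)
        back = read_raster(path)
        assert np.array_equal(back.times, raster.times)
        assert np.array_equal(back.neurons, raster.neurons)
        assert back.T == raster.T and back.s == raster.s
        assert np.array_equal(back.inhibitory, raster.inhibitory)

    def test_invariants_enforced_on_construction(self):
        with pytest.raises(ValueError):
            SpikeRaster(times=np.array([5]), neurons=np.array([0]), T=4,
                        s=0, inhibitory=np.zeros(3, dtype=bool))
        with pytest.raises(ValueError):
            SpikeRaster(times=np.array([0]), neurons=np.array([9]), T=4,
                        s=0, inhibitory=np.zeros(3, dtype=bool))
        with pytest.raises(ValueError):
            SpikeRaster(times=np.array([3, 1]), neurons=np.array([0, 1]), T=4,
                        s=0, inhibitory=np.zeros(3, dtype=bool))
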