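"""Trial summaries: rate histograms, peak statistics, validity flags,
spectral analysis against generated fixtures with known frequencies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import raster_from_events
from spikephase.metrics import (BANDS, MetricsConfig, PopulationRate,
                                classify_band, dominant_frequency,
                                is_reliable, is_sustained, last_spike_time,
                                peak_stats, population_rate, returned_to_rest,
                                summarize_trial)
from spikephase.synth import FixtureSpec, make_raster


def make_rate(counts, bin_ms=1.0):
    counts = np.asarray(counts, dtype=np.int64)
    return PopulationRate(counts=counts, bin_ms=bin_ms,
                          T=int(len(counts) * bin_ms))


class TestPopulationRate:
    def test_empty_raster_all_zero(self):
        rate = population_rate(raster_from_events([], []))
        assert rate.counts.sum() == 0

    def test_impulse_concentrates_in_first_bin(self):
        r = raster_from_events([0] * 5, range(5))
        rate = population_rate(r)
        assert rate.counts[0] == 5 and rate.counts[1:].sum() == 0

    def test_excitatory_restriction(self):
        raster = raster_from_events([0, 1, 2], [0, 1, 2], N=3)
        raster.inhibitory[2] = True
        assert population_rate(raster).counts.sum() == 2
        assert population_rate(raster, excitatory_only=False).counts.sum() == 3

    @given(st.lists(st.integers(0, 1023), max_size=200),
           st.sampled_from([1.0, 2.0, 4.0, 8.0]))
    @settings(max_examples=50, deadline=None)
    def test_spike_conservation_any_bin_width(self, times, bin_ms):
        raster = raster_from_events(sorted(times), [0] * len(times), N=1)
        rate = population_rate(raster, bin_ms=bin_ms)
        assert rate.counts.sum() == len(times)

    def test_homogeneous_fixture_mean_rate(self):
        spec = FixtureSpec(kind="homogeneous", rate_hz=10.0, n_neurons=100,
                           T=1024, seed=5)
        rate = population_rate(make_raster(spec))
        lam = 10.0 / 1000.0 * 100          # expected spikes per ms
        se = np.sqrt(lam / 1024)
        assert abs(rate.counts.mean() - lam) < 4 * se


class TestPeakAndDuration:
    def test_all_zero_series_convention(self):
        assert peak_stats(make_rate(np.zeros(10))) == (0.0, 0.0)

    def test_earliest_max_tie_rule(self):
        assert peak_stats(make_rate([0, 3, 7, 7, 1])) == (7.0, 2.0)

    def test_last_spike_time(self):
        assert last_spike_time(raster_from_events([], [])) == 0.0
        assert last_spike_time(raster_from_events([0, 17, 500], [0, 1, 2])) == 500.0


class TestFlags:
    def test_empty_raster_returned_to_rest(self):
        r = raster_from_events([], [])
        assert returned_to_rest(r) and not is_sustained(r)

    def test_late_spike_fails_rest(self):
        r = raster_from_events([0, 500], [0, 1])
        assert not returned_to_rest(r) and is_sustained(r)

    def test_boundary_spike_at_100ms_counts_as_sustained(self):
        r = raster_from_events([0, 100], [0, 1])
        assert is_sustained(r) and not returned_to_rest(r)

    @given(st.lists(st.integers(0, 1023), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_flags_complement_for_nonempty_rasters(self, times):
        r = raster_from_events(sorted(times), [0] * len(times), N=1)
        assert returned_to_rest(r) != is_sustained(r)

    def test_reliability_saturation(self):
        assert is_reliable(make_rate([10, 50, 99]), 100, saturation_fraction=1.0)
        assert not is_reliable(make_rate([10, 100, 3]), 100, saturation_fraction=1.0)
        assert is_reliable(make_rate([]), 100)

    def test_reliability_default_tolerates_isolated_neurons(self):
        # 95 of 100 firing in one bin counts as a population-wide volley
        assert not is_reliable(make_rate([95]), 100)
        assert is_reliable(make_rate([94]), 100)


class TestSpectral:
    def test_constant_series_has_no_dominant_frequency(self):
        assert dominant_frequency(make_rate([4] * 256)) is None
        assert dominant_frequency(make_rate([0] * 256)) is None

    @pytest.mark.parametrize("freq,band", [(2, "delta"), (5, "theta"),
                                           (10, "alpha"), (20, "beta"),
                                           (50, "gamma")])
    def test_sinusoid_fixture_recovers_frequency_and_band(self, freq, band):
        spec = FixtureSpec(kind="sinusoid", freq_hz=freq, amplitude=5.0,
                           T=1024, seed=freq)
        rate = population_rate(make_raster(spec))
        f = dominant_frequency(rate)
        assert f == pytest.approx(freq, abs=1000 / 1024)  # one frequency bin
        assert classify_band(f) == band

    def test_pure_sinusoid_analytic(self):
        t = np.arange(1024)
        counts = np.round(50 * (1 + np.sin(2 * np.pi * 20 * t / 1000))).astype(int)
        f = dominant_frequency(make_rate(counts))
        assert f == pytest.approx(20.0, abs=1000 / 1024)


class TestBands:
    @pytest.mark.parametrize("f,band", [(20, "beta"), (10, "alpha"),
                                        (4, "theta"), (7, "alpha"),
                                        (15, "beta"), (31, "gamma"),
                                        (0.1, "delta"), (100, "gamma"),
                                        (0.05, "none"), (150, "none")])
    def test_boundary_conventions(self, f, band):
        assert classify_band(f) == band

    @given(st.floats(min_value=0.1001, max_value=100.0))
    @settings(max_examples=200, deadline=None)
    def test_every_in_range_frequency_maps_to_exactly_one_band(self, f):
        hits = [name for name, lo, hi in BANDS if lo <= f < hi]
        if f == 100.0:
            hits.append("gamma")
        assert len(hits) == 1
        assert classify_band(f) == hits[0]


class TestSummarizeTrial:
    def test_empty_raster(self):
        s = summarize_trial(raster_from_events([], []))
        assert (s.r, s.t_last) == (0.0, 0.0)
        assert s.returned_to_rest and s.reliable
        assert s.f_dom is None and s.band is None

    def test_impulse_raster(self):
        s = summarize_trial(raster_from_events([0] * 5, range(5)))
        assert (s.r, s.t_peak, s.t_last) == (5.0, 0.0, 0.0)
        assert s.returned_to_rest

    def test_sustained_oscillator_classified(self):
        spec = FixtureSpec(kind="sinusoid", freq_hz=20, amplitude=5.0,
                           T=1024, seed=1)
        s = summarize_trial(make_raster(spec))
        assert not s.returned_to_rest
        assert s.band == "beta"

    def test_transient_burst_gets_no_band(self):
        spec = FixtureSpec(kind="burst", amplitude=5.0, tau_ms=10.0,
                           T=1024, seed=2)
        s = summarize_trial(make_raster(spec))
        assert s.returned_to_rest  # burst dead well before 100 ms
        assert s.band is None
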