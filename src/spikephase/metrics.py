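"""Per-trial summaries of a spike raster.

The response of a trial is read off the excitatory population rate — the
per-bin spike count of excitatory neurons.  From it we take the peak rate
and its time, the time of the last spike, two validity flags (return to
rest within 100 ms; reliability, i.e. the population never saturates a bin),
and, for trials with sustained activity, the dominant FFT frequency and the
brain-wave band it falls in: δ (0.1–4 Hz), θ (4–7 Hz), α (7–15 Hz),
β (15–31 Hz), γ (31–100 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import SpikeRaster

__all__ = ["MetricsConfig", "PopulationRate", "TrialSummary", "BANDS",
           "population_rate", "peak_stats", "last_spike_time",
           "returned_to_rest", "is_sustained", "is_reliable",
           "dominant_frequency", "classify_band", "summarize_trial"]

#: Band boundaries in Hz; each half-open [lo, hi) except γ which includes
#: its 100 Hz upper edge.  Boundaries shared by two bands in the common
#: naming (4, 7, 15, 31 Hz) are assigned to the upper band.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.1, 4.0),
    ("theta", 4.0, 7.0),
    ("alpha", 7.0, 15.0),
    ("beta", 15.0, 31.0),
    ("gamma", 31.0, 100.0),
)


@dataclass(frozen=True)
class MetricsConfig:
    """Knobs of the summary stage.

    bin_ms : population-rate bin width; 1 ms matches the integration step.
    rest_window_ms : a trial "returned to rest" iff its last spike falls
        before this time (and is "sustained" otherwise).
    saturation_fraction : a trial is unreliable iff some rate bin reaches
        this fraction of the excitatory population (the whole population
        firing within one bin).  The default 0.95 tolerates the handful of
        neurons that, in a small sparse realization, have no incoming
        synapse and so can never join a population-wide volley.
    excitatory_only : restrict the rate (and hence the FFT) to excitatory
        neurons; switch off to include inhibitory spikes.
    """

    bin_ms: float = 1.0
    rest_window_ms: float = 100.0
    saturation_fraction: float = 0.95
    excitatory_only: bool = True


@dataclass
class PopulationRate:
    """Spike counts per time bin (excitatory population by default)."""

    counts: np.ndarray
    bin_ms: float
    T: int

    @property
    def times(self) -> np.ndarray:
        """Left edges of the bins in ms."""
        return np.arange(len(self.counts)) * self.bin_ms


@dataclass
class TrialSummary:
    """The five per-trial statistics plus validity flags."""

    s: int
    r: float                      # max population rate (spikes/bin)
    t_peak: float                 # ms, earliest time attaining r
    t_last: float                 # ms, last spike (0 for an empty raster)
    returned_to_rest: bool
    reliable: bool
    f_dom: Optional[float] = None  # Hz, only for sustained trials
    band: Optional[str] = None
    n_spikes: int = 0


def population_rate(raster: SpikeRaster, bin_ms: float = 1.0,
                    excitatory_only: bool = True) -> PopulationRate:
    """Histogram the raster's spike times at the given bin width."""
    times = raster.excitatory_times() if excitatory_only else raster.times
    n_bins = int(np.ceil(raster.T / bin_ms))
    counts, _ = np.histogram(times, bins=n_bins, range=(0, n_bins * bin_ms))
    return PopulationRate(counts=counts.astype(np.int64), bin_ms=bin_ms, T=raster.T)


def peak_stats(rate: PopulationRate) -> tuple[float, float]:
    """Peak bin count and the earliest bin time attaining it.

    An all-zero series reports (0, 0) by convention.
    """
    if len(rate.counts) == 0 or rate.counts.max() == 0:
        return 0.0, 0.0
    k = int(np.argmax(rate.counts))  # argmax takes the earliest maximum
    return float(rate.counts[k]), float(k * rate.bin_ms)


def last_spike_time(raster: SpikeRaster) -> float:
    """Time of the final spike; 0 by convention for an empty raster."""
    return float(raster.times.max()) if raster.n_spikes else 0.0


def returned_to_rest(raster: SpikeRaster, rest_window_ms: float = 100.0) -> bool:
    """True iff the network fell silent before ``rest_window_ms``."""
    return last_spike_time(raster) < rest_window_ms if raster.n_spikes else True


def is_sustained(raster: SpikeRaster, rest_window_ms: float = 100.0) -> bool:
    """True iff any spike occurs at or after ``rest_window_ms``
    (the gate for oscillation analysis)."""
    return raster.n_spikes > 0 and last_spike_time(raster) >= rest_window_ms


def is_reliable(rate: PopulationRate, n_excitatory: int,
                saturation_fraction: float = 0.95) -> bool:
    """False iff some bin reaches the saturation fraction of the population
    — the whole excitatory population firing within a single bin."""
    if len(rate.counts) == 0:
        return True
    return bool(rate.counts.max() < saturation_fraction * n_excitatory)


def dominant_frequency(rate: PopulationRate) -> Optional[float]:
    """Frequency (Hz) of the largest non-DC component of the rate spectrum.

    The FFT is taken over the full raw series (rectangular window, no
    detrending beyond excluding the zero-frequency term).  Returns None when
    all non-DC power vanishes (constant series).  With a 1024-ms record the
    frequency resolution is ~0.98 Hz.
    """
    x = np.asarray(rate.counts, dtype=float)
    if len(x) < 2:
        return None
    spectrum = np.abs(np.fft.rfft(x))
    spectrum[0] = 0.0
    if not spectrum.max() > 0:
        return None
    fs = 1000.0 / rate.bin_ms  # Hz
    k = int(np.argmax(spectrum))
    return float(k * fs / len(x))


def classify_band(f_dom: float) -> str:
    """Map a frequency to its brain-wave band; 'none' outside (0.1, 100]."""
    for name, lo, hi in BANDS:
        if lo <= f_dom < hi:
            return name
    if f_dom == BANDS[-1][2]:  # 100 Hz belongs to γ
        return "gamma"
    return "none"


def summarize_trial(raster: SpikeRaster, s: Optional[int] = None,
                    cfg: MetricsConfig = MetricsConfig()) -> TrialSummary:
    """Bundle all per-trial statistics.

    The dominant frequency and band are computed only for sustained trials
    (activity persisting past the rest window): transient responses have no
    meaningful oscillation to classify.
    """
    rate = population_rate(raster, cfg.bin_ms, cfg.excitatory_only)
    r, t_peak = peak_stats(rate)
    t_last = last_spike_time(raster)
    rest = returned_to_rest(raster, cfg.rest_window_ms)
    reliable = is_reliable(rate, raster.n_excitatory, cfg.saturation_fraction)
    f_dom = band = None
    if is_sustained(raster, cfg.rest_window_ms):
        f_dom = dominant_frequency(rate)
        if f_dom is not None:
            band = classify_band(f_dom)
    return TrialSummary(
        s=raster.s if s is None else s,
        r=r, t_peak=t_peak, t_last=t_last,
        returned_to_rest=rest, reliable=reliable,
        f_dom=f_dom, band=band, n_spikes=raster.n_spikes,
    )
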