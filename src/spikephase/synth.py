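"""Synthetic rasters and response sequences with known ground truth.

These generators let the metrics and dynamic-range stages be tested without
running the network simulator: rasters whose population rate has a known
statistical structure (a single impulse; homogeneous random spiking at a
set rate; a sinusoid-modulated rate at a set frequency; a decaying burst),
and named response-sequence patterns with known dynamic range.

Counts are drawn per 1-ms bin (Poisson), matching the binned world of the
metrics, rather than by point-process thinning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynrange import ResponseSequence
from .engine import SpikeRaster

__all__ = ["FixtureSpec", "make_raster", "make_response_sequence"]

_KINDS = ("impulse", "homogeneous", "sinusoid", "burst")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic raster.

    kind : 'impulse' (s spikes at t=0), 'homogeneous' (per-neuron Poisson
        spiking at rate_hz), 'sinusoid' (per-bin Poisson counts with mean
        amplitude*(1+sin 2π f t)), 'burst' (per-bin Poisson counts with an
        exponentially decaying mean, time constant tau_ms)
    T : duration in ms; n_neurons : population size (all excitatory)
    """

    kind: str
    T: int = 1024
    n_neurons: int = 100
    s: int = 5                       # impulse size
    rate_hz: float = 10.0            # homogeneous per-neuron rate
    freq_hz: float = 20.0            # sinusoid modulation frequency
    amplitude: float = 5.0           # mean spikes/bin of sinusoid & burst
    tau_ms: float = 20.0             # burst decay constant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; one of {_KINDS}")
        if self.T < 1 or self.n_neurons < 1:
            raise ValueError("T and n_neurons must be positive")
        if self.kind == "impulse" and not 0 <= self.s <= self.n_neurons:
            raise ValueError("impulse size s must lie in [0, n_neurons]")
        if min(self.rate_hz, self.freq_hz, self.amplitude, self.tau_ms) < 0:
            raise ValueError("rates, frequencies and amplitudes must be >= 0")


def _raster_from_counts(counts: np.ndarray, spec: FixtureSpec,
                        rng: np.random.Generator) -> SpikeRaster:
    times = np.repeat(np.arange(len(counts), dtype=np.int64), counts)
    neurons = rng.integers(0, spec.n_neurons, size=len(times))
    return SpikeRaster(times=times, neurons=neurons, T=spec.T,
                       s=0, inhibitory=np.zeros(spec.n_neurons, dtype=bool),
                       meta={"fixture": spec})


def make_raster(spec: FixtureSpec) -> SpikeRaster:
    """Generate a raster with the specified structure; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    t_ms = np.arange(spec.T, dtype=float)
    if spec.kind == "impulse":
        neurons = np.arange(spec.s, dtype=np.int64)
        return SpikeRaster(times=np.zeros(spec.s, dtype=np.int64),
                           neurons=neurons, T=spec.T, s=spec.s,
                           inhibitory=np.zeros(spec.n_neurons, dtype=bool),
                           meta={"fixture": spec})
    if spec.kind == "homogeneous":
        lam = spec.rate_hz / 1000.0 * spec.n_neurons  # spikes per ms, population
        counts = rng.poisson(lam, size=spec.T)
    elif spec.kind == "sinusoid":
        mean = spec.amplitude * (1.0 + np.sin(2 * np.pi * spec.freq_hz * t_ms / 1000.0))
        counts = rng.poisson(mean)
    else:  # burst
        mean = spec.amplitude * np.exp(-t_ms / spec.tau_ms)
        counts = rng.poisson(mean)
    return _raster_from_counts(counts, spec, rng)


#: Canonical six-point worked example: stimuli one stop apart, responses
#: (0, 0, 2, 3, 4, 4) whose largest strictly increasing subsequence
#: (0, 2, 3, 4) has length 4.
_EXAMPLE = ((0, 1, 2, 4, 8, 16), (0.0, 0.0, 2.0, 3.0, 4.0, 4.0))


def make_response_sequence(pattern: str, length: int = 10,
                           seed: Optional[int] = None) -> ResponseSequence:
    """Named response-sequence patterns with known dynamic range.

    'example'  : the canonical worked example (dynamic range 4)
    'monotone' : strictly increasing responses (dynamic range = length)
    'flat'     : constant responses (dynamic range 1)
    'random'   : seeded integer responses with ties common
    All trials are marked valid.
    """
    if pattern == "example":
        stimuli, responses = _EXAMPLE
    elif pattern == "monotone":
        stimuli = tuple(0 if i == 0 else 2 ** (i - 1) for i in range(length))
        responses = tuple(float(i) for i in range(length))
    elif pattern == "flat":
        stimuli = tuple(0 if i == 0 else 2 ** (i - 1) for i in range(length))
        responses = (1.0,) * length
    elif pattern == "random":
        rng = np.random.default_rng(seed)
        stimuli = tuple(0 if i == 0 else 2 ** (i - 1) for i in range(length))
        responses = tuple(float(x) for x in rng.integers(0, length, size=length))
    else:
        raise ValueError(f"unknown pattern {pattern!r}; "
                         "one of example|monotone|flat|random")
    return ResponseSequence(stimuli=stimuli, responses=responses,
                            valid=(True,) * len(stimuli))
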