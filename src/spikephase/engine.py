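"""Impulse-stimulation trials: force s excitatory neurons to fire at t=0,
propagate for T ms, emit the spike raster.

Synapses are instantaneous current pulses: a presynaptic spike in the 1-ms
bin t adds the edge weight to the postsynaptic input current for bin t+1
only (no delays, no conductance kinetics).  Stimulated neurons fire once at
t=0 — spike recorded, reset applied, outputs delivered — and are thereafter
ordinary neurons.  There is no external current after t=0 and no spontaneous
activity: with s=0 the network stays exactly at its resting fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network
from .neuron import (
    IntegrationConfig,
    V_PEAK,
    initial_state,
    membrane_derivative,
)

__all__ = ["StimulusProtocol", "TrialConfig", "SpikeRaster",
           "make_protocol", "run_trial", "run_protocol",
           "write_raster", "read_raster"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus magnitudes (neuron counts): 0 followed by a doubling ladder."""

    magnitudes: tuple[int, ...]

    def __post_init__(self) -> None:
        s = self.magnitudes
        if len(s) < 1 or s[0] != 0:
            raise ValueError("protocol must start with the resting stimulus s0=0")
        if len(s) > 1 and s[1] < 1:
            raise ValueError("stimuli after s0 must be positive")
        for a, b in zip(s[1:], s[2:]):
            if b != 2 * a:
                raise ValueError(
                    f"stimuli must double at each stop, got {a} -> {b}")

    def __len__(self) -> int:
        return len(self.magnitudes)

    def __iter__(self):
        return iter(self.magnitudes)


def make_protocol(s_max: int = 256) -> StimulusProtocol:
    """The one-stop (factor-of-two) ladder (0, 1, 2, 4, ..., s_max).

    ``s_max`` must be a power of two; the default 256 yields the 10-element
    protocol used throughout the sweeps.
    """
    if s_max < 1 or s_max & (s_max - 1):
        raise ValueError(f"s_max must be a power of 2, got {s_max}")
    mags = [0]
    s = 1
    while s <= s_max:
        mags.append(s)
        s *= 2
    return StimulusProtocol(tuple(mags))


@dataclass(frozen=True)
class TrialConfig:
    """Observation window T (ms), integration scheme, stimulus-selection seed."""

    T: int = 1024
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    stim_seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")


@dataclass
class SpikeRaster:
    """Spike events of one trial: parallel arrays of (ms bin, neuron index).

    ``inhibitory`` records the phenotype of every neuron in the network so
    downstream metrics can restrict to the excitatory population.
    """

    times: np.ndarray
    neurons: np.ndarray
    T: int
    s: int
    inhibitory: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.neurons = np.asarray(self.neurons, dtype=np.int64)
        if len(self.times) != len(self.neurons):
            raise ValueError("times and neurons must have equal length")
        if len(self.times) and (self.times.min() < 0 or self.times.max() >= self.T):
            raise ValueError("spike times must lie in [0, T)")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be non-decreasing")
        N = len(self.inhibitory)
        if len(self.neurons) and (self.neurons.min() < 0 or self.neurons.max() >= N):
            raise ValueError("neuron indices must lie in [0, N)")

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    @property
    def n_excitatory(self) -> int:
        return int(np.sum(~self.inhibitory))

    def excitatory_times(self) -> np.ndarray:
        return self.times[~self.inhibitory[self.neurons]]


def run_trial(net: Network, s: int, cfg: TrialConfig = TrialConfig()) -> SpikeRaster:
    """Simulate one impulse trial from the resting state.

    Exactly ``s`` distinct excitatory neurons (a uniform random subset under
    ``cfg.stim_seed``) fire at t=0; the network then evolves freely.  The run
    is bit-for-bit deterministic given (network, s, cfg).
    """
    exc = net.excitatory_indices
    if s > len(exc):
        raise ValueError(f"s={s} exceeds the {len(exc)} excitatory neurons")
    N = net.N
    rest = initial_state()
    v = np.full(N, rest.v, dtype=np.float64)
    u = np.full(N, rest.u, dtype=np.float64)
    a = np.where(net.inhibitory, net.params_inhibitory.a, net.params_excitatory.a)
    b = np.where(net.inhibitory, net.params_inhibitory.b, net.params_excitatory.b)
    c = np.where(net.inhibitory, net.params_inhibitory.c, net.params_excitatory.c)
    d = np.where(net.inhibitory, net.params_inhibitory.d, net.params_excitatory.d)

    W_T = net.weights.T.tocsr()  # postsynaptic input = W^T @ spike vector

    times: list[np.ndarray] = []
    neurons: list[np.ndarray] = []

    # t = 0: forced firing of the stimulated subset, then reset + delivery.
    rng = np.random.default_rng(cfg.stim_seed)
    stim = rng.choice(exc, size=s, replace=False) if s > 0 else np.empty(0, int)
    fired = np.zeros(N, dtype=bool)
    fired[stim] = True
    if s > 0:
        order = np.sort(stim)
        times.append(np.zeros(s, dtype=np.int64))
        neurons.append(order)
        v[stim] = c[stim]
        u[stim] = u[stim] + d[stim]

    icfg = cfg.integration
    h = icfg.dt / icfg.substeps
    for t in range(1, cfg.T):
        I = W_T @ fired.astype(np.float64) if fired.any() else np.zeros(N)
        spiked = np.zeros(N, dtype=bool)
        for _ in range(icfg.substeps):
            active = ~spiked
            v[active] = v[active] + h * membrane_derivative(v[active], u[active], I[active])
            crossing = active & (v > V_PEAK)
            v[crossing] = V_PEAK
            spiked |= crossing
        u += icfg.dt * a * (b * v - u)
        v[spiked] = c[spiked]
        u[spiked] += d[spiked]
        if not np.all(np.isfinite(v)) or not np.all(np.isfinite(u)):
            raise FloatingPointError(
                f"non-finite membrane state at t={t} ms; reduce dt")
        if spiked.any():
            idx = np.flatnonzero(spiked)
            times.append(np.full(len(idx), t, dtype=np.int64))
            neurons.append(idx)
        fired = spiked

    all_t = np.concatenate(times) if times else np.empty(0, dtype=np.int64)
    all_n = np.concatenate(neurons) if neurons else np.empty(0, dtype=np.int64)
    return SpikeRaster(
        times=all_t, neurons=all_n, T=cfg.T, s=int(s),
        inhibitory=net.inhibitory.copy(),
        meta={"network": net.config, "stim_seed": cfg.stim_seed},
    )


def run_protocol(net: Network, proto: StimulusProtocol,
                 cfg: TrialConfig = TrialConfig()) -> list[SpikeRaster]:
    """One independent trial per stimulus, each from identical resting
    initial conditions (trials never run back-to-back)."""
    exc_count = net.n_excitatory
    if max(proto) > exc_count:
        raise ValueError(
            f"largest stimulus {max(proto)} exceeds {exc_count} excitatory neurons")
    return [run_trial(net, s, cfg) for s in proto]


def write_raster(raster: SpikeRaster, path) -> None:
    """Two-column plain text (ms, neuron-id) with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# T={raster.T} s={raster.s} N={len(raster.inhibitory)}\n")
        fh.write("# inhibitory=" +
                 ",".join(map(str, np.flatnonzero(raster.inhibitory))) + "\n")
        for t, n in zip(raster.times, raster.neurons):
            fh.write(f"{t}\t{n}\n")


def read_raster(path) -> SpikeRaster:
    """Inverse of :func:`write_raster`."""
    with open(path) as fh:
        meta = dict(kv.split("=") for kv in fh.readline().lstrip("# ").split())
        inhib_line = fh.readline().lstrip("# ").strip()
        inhib_idx = [int(x) for x in inhib_line.split("=", 1)[1].split(",") if x]
        pairs = [line.split() for line in fh if line.strip()]
    N = int(meta["N"])
    inhibitory = np.zeros(N, dtype=bool)
    inhibitory[inhib_idx] = True
    times = np.array([int(p[0]) for p in pairs], dtype=np.int64)
    neurons = np.array([int(p[1]) for p in pairs], dtype=np.int64)
    return SpikeRaster(times=times, neurons=neurons, T=int(meta["T"]),
                       s=int(meta["s"]), inhibitory=inhibitory)
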