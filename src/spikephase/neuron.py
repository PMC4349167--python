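"""Two-variable Izhikevich neuron: dynamics, spike reset, canonical phenotypes.

The model couples a fast membrane potential ``v`` (mV) to a slow recovery
variable ``u`` (same native units) through

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with the discontinuous after-spike rule: whenever ``v`` exceeds 30 mV the
neuron is said to have spiked and its state is reset to ``v <- c``,
``u <- u + d``.  All quantities are in the model's native mV/ms units; the
input current ``I`` is on the same scale as the voltage dynamics.

Two phenotypes are used throughout the package: regular spiking (adapting,
excitatory) and fast spiking (high-rate, inhibitory).  With their shared
initial condition ``(v, u) = (-70, -14)`` and ``I = 0`` the dynamics sit on
an exact fixed point, so an unstimulated neuron is silent forever: the model
has no spontaneous activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "V_PEAK",
    "NeuronParams",
    "NeuronState",
    "IntegrationConfig",
    "regular_spiking_params",
    "fast_spiking_params",
    "initial_state",
    "membrane_derivative",
    "recovery_derivative",
    "step",
    "simulate_single",
]

#: Spike cutoff (mV).  Crossing this value triggers the after-spike reset.
V_PEAK = 30.0


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich phenotype parameters.

    a : recovery time scale (1/ms), a > 0
    b : sensitivity of recovery to subthreshold voltage (dimensionless)
    c : after-spike reset potential (mV), must lie below the 30 mV cutoff
    d : after-spike recovery increment
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"recovery time scale a must be > 0, got {self.a}")
        if not self.c < V_PEAK:
            raise ValueError(f"reset potential c must be < {V_PEAK} mV, got {self.c}")


@dataclass
class NeuronState:
    """Membrane potential v (mV) and recovery variable u."""

    v: float
    u: float


@dataclass(frozen=True)
class IntegrationConfig:
    """Forward-Euler stepping scheme.

    dt : outer step in ms; spikes are recorded on this grid.
    substeps : inner subdivisions of dt applied to the voltage equation
        (u is advanced once per outer step, the convention of the model's
        original published code).
    """

    dt: float = 1.0
    substeps: int = 2

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.substeps < 1:
            raise ValueError(f"substeps must be >= 1, got {self.substeps}")


def regular_spiking_params() -> NeuronParams:
    """Parameters of the regular-spiking (excitatory) phenotype."""
    return NeuronParams(a=0.02, b=0.2, c=-65.0, d=8.0)


def fast_spiking_params() -> NeuronParams:
    """Parameters of the fast-spiking (inhibitory) phenotype."""
    return NeuronParams(a=0.10, b=0.2, c=-65.0, d=2.0)


def initial_state() -> NeuronState:
    """Tabulated initial condition (v=-70 mV, u=-14); a fixed point at I=0."""
    return NeuronState(v=-70.0, u=-14.0)


def membrane_derivative(v, u, I):
    """dv/dt of the voltage equation; accepts scalars or arrays."""
    return 0.04 * v * v + 5.0 * v + 140.0 - u + I


def recovery_derivative(v, u, params: NeuronParams):
    """du/dt of the recovery equation; accepts scalars or arrays."""
    return params.a * (params.b * v - u)


def step(
    state: NeuronState,
    params: NeuronParams,
    I: float,
    cfg: IntegrationConfig = IntegrationConfig(),
) -> tuple[NeuronState, bool]:
    """Advance one neuron by ``cfg.dt`` ms; return (new state, spiked flag).

    The voltage is advanced in ``cfg.substeps`` Euler sub-increments with u
    held fixed, checking the 30 mV cutoff after each; u is then advanced once
    over the full dt.  On a spike the voltage is clamped to the cutoff for
    the remainder of the step (cosmetic, for raster consistency) and the
    reset ``v <- c``, ``u <- u + d`` is applied at the end of the step.  A
    state already above the cutoff on entry is reset immediately.
    """
    v, u = float(state.v), float(state.u)
    if v > V_PEAK:
        return NeuronState(v=params.c, u=u + params.d), True
    h = cfg.dt / cfg.substeps
    spiked = False
    for _ in range(cfg.substeps):
        if not spiked:
            v = v + h * membrane_derivative(v, u, I)
            if v > V_PEAK:
                v = V_PEAK
                spiked = True
    u = u + cfg.dt * recovery_derivative(v, u, params)
    if spiked:
        v = params.c
        u = u + params.d
    if not (math.isfinite(v) and math.isfinite(u)):
        raise FloatingPointError(
            f"non-finite neuron state after step (v={v}, u={u}); "
            "reduce dt or check the input current"
        )
    return NeuronState(v=v, u=u), spiked


def simulate_single(
    params: NeuronParams,
    I_series,
    T: int,
    cfg: IntegrationConfig = IntegrationConfig(),
    state: NeuronState | None = None,
) -> list[int]:
    """Drive a single neuron for T ms and return its sorted spike times.

    ``I_series`` is the input current per 1-ms bin: a scalar (constant
    current) or a sequence of length >= T.  Spike times are the outer-step
    bin indices in [0, T).  The run is exactly deterministic.
    """
    if T < 0:
        raise ValueError(f"duration T must be >= 0, got {T}")
    if state is None:
        state = initial_state()
    currents = np.broadcast_to(np.asarray(I_series, dtype=float), (max(T, 1),)) \
        if np.ndim(I_series) == 0 else np.asarray(I_series, dtype=float)
    if T > 0 and len(currents) < T:
        raise ValueError(f"I_series has {len(currents)} entries, need {T}")
    spikes: list[int] = []
    for t in range(T):
        state, fired = step(state, params, float(currents[t]), cfg)
        if fired:
            spikes.append(t)
    return spikes
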