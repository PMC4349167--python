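# Methods

## Model

Each neuron follows the two-variable quadratic model

    dv/dt = 0.04 v² + 5 v + 140 − u + I
    du/dt = a (b v − u)
    if v > 30 mV:  v ← c,  u ← u + d

with all quantities in the model's native mV/ms units.  Excitatory neurons
use the regular-spiking parameter set (a, b, c, d) = (0.02, 0.2, −65, 8),
inhibitory neurons the fast-spiking set (0.10, 0.2, −65, 2); both start at
(v, u) = (−70, −14).  That initial condition solves both right-hand sides
at I = 0, so an unstimulated neuron — and hence an unstimulated network —
is silent for the whole run.  The model has no noise term and no background
drive: "resting state" is operationalized as literally zero spikes.

The network is a directed Erdős–Rényi graph on N neurons: every ordered
pair (i, j), i ≠ j, carries a synapse independently with probability p (an
undirected, symmetrized variant is available behind a config switch; the
directed interpretation is the default because chemical synapses are
directional).  Which N_i neurons are inhibitory is a uniform random index
subset.  All outgoing synapses of an excitatory neuron share one weight
w_e ≥ 0; all outgoing synapses of an inhibitory neuron share w_i ≤ 0.
No weight distributions, delays, or plasticity.

### Synapse convention

The coupling is an instantaneous current pulse: a presynaptic spike in
1-ms bin t adds the edge weight to the postsynaptic input current during
bin t+1 only.  This is the simplest convention consistent with treating
(w_e, w_i) as bare sweep axes.  Any other synapse model (exponential
currents, conductances, delays) rescales the weight axes — the absolute
weight values in our diagrams are convention-dependent; the qualitative
region structure is the reproducible object.

### Integration

Forward Euler with an outer step dt = 1 ms.  The voltage equation is
advanced in `substeps` = 2 half-steps with u held, then u is advanced once
over the full dt — the convention of the model's original published code.
The 30 mV cutoff is checked after each half-step; on a crossing the voltage
is clamped to 30 for the remainder of the step (cosmetic, so rasters and
traces never show overshoot; u is never clamped) and the reset is applied
at the end of the step.  Spike times are recorded at the enclosing 1-ms
bin.  A non-finite state raises instead of being silently repaired.  The
scheme is a config knob (`IntegrationConfig`); the neuron tests document
the residual Euler sensitivity (the I = 10 spike count moves by ≤ 10%
between 2 and 4 substeps) rather than hiding it.

Floating-point note: 0.04·70² + 5·(−70) + 140 + 14 is zero analytically
but leaves ~3·10⁻¹⁴ of coefficient-rounding residue in binary arithmetic;
over 1024 ms the resting trajectory therefore holds |v + 70| < 10⁻⁹ rather
than bit-exact equality, and tests assert it at that tolerance.

## Stimulation protocol and trial structure

A trial forces s distinct excitatory neurons (a uniform random,
seed-controlled subset) to fire once at t = 0: the spike is recorded, the
reset applied, and their synaptic output delivered — afterwards they are
ordinary neurons.  The network then runs freely for T = 1024 ms with no
external current.  A protocol is the one-stop ladder
s ∈ (0, 1, 2, 4, …, s_max) — consecutive stimuli differ by a factor of two,
i.e. one photographic stop — and every trial restarts from the resting
state (trials are independent, not sequential).

## Per-trial statistics

The excitatory population rate is the per-1-ms-bin spike count of
excitatory neurons (bin width and the excitatory-only restriction are
config; 1 ms matches the integration step).  From it:

- r — peak rate; ties broken by the earliest bin; the response of the trial.
- t_peak — time of that peak (0 for an empty raster, by convention).
- t_last — time of the last spike (0 for an empty raster).
- returned_to_rest — t_last < 100 ms.  The 100-ms window is the
  operational "acceptable time" for returning to rest and is config.
- reliable — no bin reaches `saturation_fraction` × (excitatory count).
  Saturation means the whole population fires inside one bin and the
  response ceases to discriminate stimuli.  Default 0.95 rather than 1.0:
  in a small sparse realization (N·p of order a few) the expected number
  of excitatory neurons with zero in-degree is O(1), and such neurons can
  never join a volley, so an exact-count ceiling would be unattainable
  even in fully saturated dynamics.  At N = 1000, p ≥ 0.01 the two
  choices almost always coincide.
- f_dom, band — for sustained trials only (a spike at ≥ 100 ms): the
  frequency of the largest non-DC component of the raw rate spectrum
  (rectangular window, full record; ~0.98 Hz resolution at 1024 ms), and
  its brain-wave band δ [0.1, 4), θ [4, 7), α [7, 15), β [15, 31),
  γ [31, 100] Hz.  Shared boundary frequencies are assigned to the upper
  band — arbitrary but fixed.  The 1-s record genuinely limits δ/θ
  resolution.

## Dynamic range

Over a protocol, the responses form R = (r(s₀), …, r(s_n)).  The dynamic
range is the number of elements of the largest subsequence of R — standard
order-preserving, not necessarily contiguous — that (i) is strictly
increasing in r and (ii) uses only valid trials (returned to rest and
reliable; both failure modes are excluded alike).  Strict monotonicity over
one-stop-spaced stimuli enforces a just-noticeable difference of ≤ 1 stop,
making the statistic a lower bound on the true dynamic range in stops.  It
is computed as a longest-strictly-increasing-subsequence (O(n²) dynamic
program, n ≤ 10) and cross-checked in the tests against exhaustive
subsequence enumeration.  Worked example: stimuli (0, 1, 2, 4, 8, 16) with
responses (0, 0, 2, 3, 4, 4) → the largest admissible subsequence is
(0, 2, 3, 4) → dynamic range 4.  Bounds: 1 (flat response, any valid
trial) to the protocol length (strictly increasing response); 0 only when
no trial is valid.

## Sweeps and phase diagrams

The sweep is brute force over (N_i, p, w_e, w_i) with a few network
realizations per point (default 3; the count is config).  Default axes:
N = 1000, N_i ∈ {100, …, 500}, p ∈ {0.01, 0.02, 0.04, 0.08, 0.16}; weight
points are either an explicit grid or uniform random draws over rectangles
(default w_e ∈ [0, 200], w_i ∈ [−200, 0] — chosen empirically to straddle
the quiescent→saturated transition and to contain the sustained-oscillation
region under our synapse convention; prominent config, not constants).
Records accumulate in a flat table keyed by every coordinate and seed, so a
sweep can be extended with new weight points later (`--resume`) without
touching existing rows.

Phase diagrams bin the (w_e, w_i) plane into pointy-top hexagons (both
axes normalized to [0, 1] over the data span so the lattice is isotropic;
hexagon size defaults to 1/20 of the span) and color each occupied hexagon
by the median of the metric over its records, faceting panels by p and N_i.
Validity rules per metric: the dynamic-range diagram uses one value per
realization and drops realizations with no valid stimulated trial (the
resting trial is trivially valid and alone cannot color a cell — otherwise
the saturated corner could never go white); the band diagram uses only
reliable, sustained trials, with the median taken as the lower median on
the ordinal scale δ < θ < α < β < γ; the duration diagram drops unreliable
trials; peak rate and peak time use every trial.  Empty or all-invalid
hexagons are drawn white.

## Synthetic fixtures

The generator produces rasters whose population rate has known structure,
so the metrics stage is testable without the simulator: an impulse
(s spikes at t = 0), homogeneous spiking (per-bin Poisson counts at a set
population rate), a sinusoid-modulated rate (per-bin Poisson counts with
mean A·(1 + sin 2πft) — the spectral oracle at 2/5/10/20/50 Hz), and a
decaying burst.  Defaults (A = 5 spikes/bin, 100 neurons, T = 1024 ms) put
the sinusoid's spectral line ~30× above the Poisson noise floor.  These
fixtures emulate rate statistics only — no refractoriness, no correlations
between neurons, no network causality — so passing metric tests says
nothing about simulator correctness; the engine has its own oracle tests
(scalar-vs-vectorized agreement, uncoupled-network exactness).

## Problem sizes

The committed analyses run a reduced design — N = 300 with 20% inhibitory
neurons, a coarse 5×5 weight grid, one realization, s_max = 128 (with 240
excitatory neurons the ladder cannot reach 256) — which reproduces the
qualitative phase structure: a saturated/unreliable corner at high w_e and
weak inhibition, white in the dynamic-range diagram; a sustained-activity
region at strong inhibition; α/β oscillations concentrated near the
excitation–inhibition balance, with β the most common non-δ band; and a
low-w_e floor whose dynamic range is high regardless of w_i.  The full
default `SweepConfig` (N = 1000, 5 × 5 facets, random weight sampling,
3 realizations) is the same code path at larger n.

## Known limitations

- Absolute weight-axis positions depend on the instantaneous-pulse synapse
  convention; only the region topology is portable.
- Forward Euler at dt = 1 ms distorts high-rate spike timing; the substep
  sensitivity is quantified but not eliminated.
- One second of simulation cannot resolve δ/θ rhythms well.
- The dominant-frequency estimator takes the single largest FFT bin; slow
  envelopes can hand δ the label in long ragged transients.
- Only the regular-spiking/fast-spiking phenotype pair is implemented; no
  chattering or bursting variants, no synaptic delays, no distributions
  over weights.
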