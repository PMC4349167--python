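"""The dynamic-range statistic of an impulse-response sequence.

A network is probed with stimuli spaced one stop (a factor of two) apart;
each stimulus s evokes a response r(s), the peak excitatory population rate
of that trial.  The dynamic range is the number of elements in the largest
stimulus-order-preserving, strictly increasing subsequence of responses
drawn only from valid trials (trials that returned to rest and were
reliable).  Strictness encodes a just-noticeable difference of at most one
stop, so the statistic is a lower bound on the network's true dynamic range
in stops.  It is at least 1 whenever any valid trial exists and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from .engine import StimulusProtocol, TrialConfig, run_protocol
from .metrics import MetricsConfig, summarize_trial
from .network import Network

__all__ = ["ResponseSequence", "dynamic_range", "brute_force_dynamic_range",
           "protocol_dynamic_range"]


@dataclass(frozen=True)
class ResponseSequence:
    """Stimulus-aligned responses with per-trial validity flags.

    stimuli : the protocol magnitudes, in stimulation order
    responses : r(s) for each stimulus
    valid : per trial, returned_to_rest AND reliable
    """

    stimuli: tuple[int, ...]
    responses: tuple[float, ...]
    valid: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not (len(self.stimuli) == len(self.responses) == len(self.valid)):
            raise ValueError("stimuli, responses and valid must align")

    def __len__(self) -> int:
        return len(self.stimuli)


def dynamic_range(seq: ResponseSequence) -> int:
    """Length of the longest strictly increasing subsequence of valid
    responses, preserving stimulus order.

    Equal responses break strict monotonicity (the just-noticeable-
    difference constraint), so a flat sequence scores 1.  With no valid
    trial the statistic is 0.
    """
    if len(seq) == 0:
        raise ValueError("response sequence is empty")
    r = [resp for resp, ok in zip(seq.responses, seq.valid) if ok]
    if not r:
        return 0
    # O(n^2) longest-strictly-increasing-subsequence; n <= protocol length.
    best = [1] * len(r)
    for j in range(len(r)):
        for i in range(j):
            if r[i] < r[j]:
                best[j] = max(best[j], best[i] + 1)
    return max(best)


def brute_force_dynamic_range(seq: ResponseSequence) -> int:
    """Exhaustive-enumeration oracle for :func:`dynamic_range`.

    Checks every subsequence of the valid trials for strict monotonicity;
    guarded to length <= 20.
    """
    if len(seq) == 0:
        raise ValueError("response sequence is empty")
    if len(seq) > 20:
        raise ValueError(f"brute force guarded to length 20, got {len(seq)}")
    r = [resp for resp, ok in zip(seq.responses, seq.valid) if ok]
    longest = 0
    for k in range(1, len(r) + 1):
        for combo in combinations(r, k):
            if all(x < y for x, y in zip(combo, combo[1:])):
                longest = k
                break
    return longest


def protocol_dynamic_range(
    net: Network,
    proto: StimulusProtocol,
    trial_cfg: TrialConfig = TrialConfig(),
    metrics_cfg: MetricsConfig = MetricsConfig(),
) -> tuple[int, ResponseSequence]:
    """Run the full protocol on a network and score its dynamic range.

    Returns the statistic together with the underlying response sequence
    (peak excitatory rate and validity per trial) for provenance.
    """
    rasters = run_protocol(net, proto, trial_cfg)
    summaries = [summarize_trial(r, cfg=metrics_cfg) for r in rasters]
    seq = ResponseSequence(
        stimuli=tuple(proto),
        responses=tuple(s.r for s in summaries),
        valid=tuple(s.returned_to_rest and s.reliable for s in summaries),
    )
    return dynamic_range(seq), seq
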