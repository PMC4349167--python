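#!/usr/bin/env python
"""The reduced brute-force sweep behind the phase diagrams.

Sweeps a coarse (w_e, w_i) grid at N=300 with 20% inhibitory neurons for
two sparseness values and two inhibitory counts (a scaled-down version of
the full 1000-neuron, 5x5-facet design; the full grid is the same call with
the default SweepConfig).  Writes the flat records table under results/ and
prints the occupancy of the three qualitative regimes: the saturated
(unreliable) corner, the sustained-activity region, and the band counts of
the oscillating trials.
"""

import time
from pathlib import Path

from spikephase.sweep import SweepConfig, run_sweep

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = SweepConfig(
        N=300,
        N_i_list=(30, 60),
        p_list=(0.02, 0.08),
        w_e_grid=(10.0, 50.0, 100.0, 150.0, 200.0),
        w_i_grid=(0.0, -50.0, -100.0, -150.0, -200.0),
        realizations=1,
        s_max=128,
        T=1024,
        seed=1,
    )
    t0 = time.time()
    records = run_sweep(cfg, progress=True)
    OUT.mkdir(parents=True, exist_ok=True)
    records.to_csv(OUT / "sweep_records.csv", index=False)
    print(f"\n{len(records)} trial records in {time.time() - t0:.0f} s "
          f"-> {OUT}/sweep_records.csv")

    stim = records[records.s >= 1]
    unrel = stim[~stim.reliable]
    sust = stim[~stim.returned_to_rest]
    print(f"unreliable trials: {len(unrel)} "
          f"(mean w_e {unrel.w_e.mean():.0f}, mean w_i {unrel.w_i.mean():.0f})")
    print(f"sustained trials: {len(sust)} "
          f"(mean w_e {sust.w_e.mean():.0f}, mean w_i {sust.w_i.mean():.0f})")
    bands = stim.loc[stim.reliable, "band"].value_counts()
    print("dominant bands among reliable sustained trials:")
    print(bands.to_string())


if __name__ == "__main__":
    main()
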