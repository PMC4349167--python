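#!/usr/bin/env python
"""Render the five phase diagrams from the sweep records.

Reads results/sweep_records.csv (written by 02_reduced_sweep.py) and draws
one faceted hexbin figure per metric: dynamic range, dominant band,
activity duration (last spike), peak rate, and peak time.  Hexagons with no
valid data stay white; numeric metrics use a sequential red scale, the band
metric the five brain-wave colors.
"""

from pathlib import Path

import pandas as pd

from spikephase.sweep import METRICS, hexbin_aggregate, render_phase_diagram

OUT = Path(__file__).resolve().parent.parent / "results"

TITLES = {
    "dr": "dynamic range (stimuli)",
    "band": "dominant oscillation band",
    "t_last": "time of last spike (ms)",
    "r_max": "peak population rate (spikes/ms)",
    "t_peak": "time of peak rate (ms)",
}


def main() -> None:
    records = pd.read_csv(OUT / "sweep_records.csv")
    n_stimuli = records.groupby("s").ngroups
    for metric in METRICS:
        table = hexbin_aggregate(records, metric, hex_size_frac=1 / 10)
        if table.table.empty:
            print(f"{metric}: no valid records, skipped")
            continue
        path = OUT / f"phase_{metric}.png"
        kwargs = {}
        if metric == "dr":
            kwargs = dict(vmin=0.0, vmax=float(n_stimuli))
        render_phase_diagram(table, path, title=TITLES[metric], **kwargs)
        print(f"{metric}: {len(table.table)} occupied hexagons -> {path}")


if __name__ == "__main__":
    main()
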