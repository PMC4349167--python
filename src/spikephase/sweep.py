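"""Brute-force parameter sweeps and hexbin phase diagrams.

A sweep walks the 4-D space (N_i, p, w_e, w_i) with a handful of network
realizations per point, runs the full impulse protocol on each realization,
and records one row per trial (plus the realization's dynamic range) in a
flat table keyed by all coordinates and seeds — so a sweep can always be
extended with new weight points later without touching existing rows.

Phase diagrams aggregate the table over hexagonal bins in the (w_e, w_i)
plane (median within each hexagon, empty or all-invalid bins left white)
and facet the panels by sparseness p and inhibitory count N_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dynrange import ResponseSequence, dynamic_range
from .engine import TrialConfig, make_protocol, run_protocol
from .metrics import BANDS, MetricsConfig, summarize_trial
from .network import NetworkConfig, build_network
from .neuron import IntegrationConfig

__all__ = ["SweepConfig", "run_sweep", "hexbin_aggregate",
           "PhaseDiagramTable", "render_phase_diagram", "METRICS"]

#: Metrics a phase diagram can display, with the validity rule deciding
#: which rows a hexagon may aggregate (white when none survive).
METRICS = {
    # dynamic range: a realization contributes only if at least one
    # stimulated (s >= 1) trial was valid; the resting trial is trivially
    # valid and alone cannot color a cell
    "dr": dict(column="dr", per="realization", valid="n_valid_stim >= 1"),
    # dominant band: only sustained, reliable trials carry an oscillation
    "band": dict(column="band", per="trial", valid="band in bands"),
    # activity duration: unreliable trials are excluded
    "t_last": dict(column="t_last", per="trial", valid="reliable"),
    # peak rate and its timing: every simulated trial counts
    "r_max": dict(column="r", per="trial", valid="any"),
    "t_peak": dict(column="t_peak", per="trial", valid="any"),
}

_BAND_ORDER = [name for name, _, _ in BANDS]


@dataclass(frozen=True)
class SweepConfig:
    """The brute-force grid.

    Weight points are either an explicit grid (``w_e_grid`` x ``w_i_grid``)
    or ``n_weight_samples`` uniform random points over the rectangles
    ``w_e_range`` x ``w_i_range`` ("chosen randomly, to cover the region of
    interest").  The default ranges straddle the quiescent-to-saturated
    transition of the default networks.  ``seed`` is the master key: every
    network realization and stimulus choice derives its own stream from it.
    """

    N: int = 1000
    N_i_list: tuple[int, ...] = (100, 200, 300, 400, 500)
    p_list: tuple[float, ...] = (0.01, 0.02, 0.04, 0.08, 0.16)
    w_e_range: tuple[float, float] = (0.0, 200.0)
    w_i_range: tuple[float, float] = (-200.0, 0.0)
    n_weight_samples: int = 64
    w_e_grid: Optional[tuple[float, ...]] = None
    w_i_grid: Optional[tuple[float, ...]] = None
    realizations: int = 3
    T: int = 1024
    s_max: int = 256
    seed: int = 0
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)

    def __post_init__(self) -> None:
        if not self.N_i_list or not self.p_list:
            raise ValueError("N_i_list and p_list must be non-empty")
        if self.w_e_range[0] < 0:
            raise ValueError("w_e range must lie in [0, inf)")
        if self.w_i_range[1] > 0:
            raise ValueError("w_i range must lie in (-inf, 0]")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")

    def weight_points(self) -> np.ndarray:
        """(n, 2) array of (w_e, w_i) points, deterministic per seed."""
        if self.w_e_grid is not None and self.w_i_grid is not None:
            pts = [(we, wi) for we in self.w_e_grid for wi in self.w_i_grid]
            return np.asarray(pts, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x5EED]))
        we = rng.uniform(*self.w_e_range, size=self.n_weight_samples)
        wi = rng.uniform(self.w_i_range[0], self.w_i_range[1],
                         size=self.n_weight_samples)
        return np.column_stack([we, wi])


def _child_seed(master: int, *key: int) -> int:
    """Deterministic 31-bit child seed from the master seed and coordinates."""
    ss = np.random.SeedSequence([master, *key])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_sweep(cfg: SweepConfig, progress: bool = False) -> pd.DataFrame:
    """Run the whole grid; one row per (N_i, p, weight point, realization,
    stimulus), each carrying the trial summary and the realization's
    dynamic range.  Fully seeded: rerunning with the same config reproduces
    the table bit-for-bit.  Failing parameter points (numerical blow-up)
    are recorded with ``error`` set and skipped, not fatal.
    """
    weights = cfg.weight_points()
    proto = make_protocol(cfg.s_max)
    rows: list[dict] = []
    for N_i in cfg.N_i_list:
        for p in cfg.p_list:
            for k, (w_e, w_i) in enumerate(weights):
                for real in range(cfg.realizations):
                    net_seed = _child_seed(cfg.seed, N_i, int(round(p * 1e6)), k, real, 0)
                    stim_seed = _child_seed(cfg.seed, N_i, int(round(p * 1e6)), k, real, 1)
                    coords = dict(N=cfg.N, N_i=N_i, p=p, w_e=float(w_e),
                                  w_i=float(w_i), weight_point=k,
                                  realization=real, net_seed=net_seed,
                                  stim_seed=stim_seed)
                    try:
                        net = build_network(NetworkConfig(
                            N=cfg.N, N_i=N_i, p=p, w_e=float(w_e),
                            w_i=float(w_i), seed=net_seed))
                        tcfg = TrialConfig(T=cfg.T, integration=cfg.integration,
                                           stim_seed=stim_seed)
                        summaries = [summarize_trial(ras, cfg=cfg.metrics)
                                     for ras in run_protocol(net, proto, tcfg)]
                        seq = ResponseSequence(
                            stimuli=tuple(proto),
                            responses=tuple(s.r for s in summaries),
                            valid=tuple(s.returned_to_rest and s.reliable
                                        for s in summaries))
                        dr = dynamic_range(seq)
                        n_valid_stim = sum(
                            ok for s, ok in zip(seq.stimuli, seq.valid) if s >= 1)
                        for summ in summaries:
                            rows.append({**coords, "s": summ.s, "r": summ.r,
                                         "t_peak": summ.t_peak,
                                         "t_last": summ.t_last,
                                         "returned_to_rest": summ.returned_to_rest,
                                         "reliable": summ.reliable,
                                         "f_dom": summ.f_dom, "band": summ.band,
                                         "n_spikes": summ.n_spikes,
                                         "dr": dr,
                                         "n_valid_stim": n_valid_stim,
                                         "error": ""})
                    except FloatingPointError as exc:
                        rows.append({**coords, "s": -1, "error": str(exc)})
                if progress:
                    print(f"N_i={N_i} p={p} done {len(weights)} weight points",
                          flush=True)
    return pd.DataFrame(rows)


@dataclass
class PhaseDiagramTable:
    """Hexbin-aggregated medians, one row per occupied hexagon per facet.

    Columns: N_i, p, q, r (axial hex coordinates), w_e, w_i (hexagon
    center), count, value.  Hexagons with no valid record are absent
    (rendered white).
    """

    table: pd.DataFrame
    metric: str
    hex_size: tuple[float, float]      # in normalized axis units
    w_e_span: tuple[float, float]
    w_i_span: tuple[float, float]


def _hex_assign(x: np.ndarray, y: np.ndarray, size: float) -> tuple[np.ndarray, np.ndarray]:
    """Axial (q, r) cell indices of pointy-top hexagons with center-to-vertex
    distance ``size``, via fractional axial coordinates and cube rounding."""
    qf = (np.sqrt(3.0) / 3.0 * x - y / 3.0) / size
    rf = (2.0 / 3.0 * y) / size
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq, dr, ds = np.abs(q - qf), np.abs(r - rf), np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q[fix_q] = -r[fix_q] - s[fix_q]
    r[fix_r] = -q[fix_r] - s[fix_r]
    return q.astype(int), r.astype(int)


def _hex_center(q: np.ndarray, r: np.ndarray, size: float) -> tuple[np.ndarray, np.ndarray]:
    x = size * np.sqrt(3.0) * (q + r / 2.0)
    y = size * 1.5 * r
    return x, y


def _valid_mask(records: pd.DataFrame, metric: str) -> pd.Series:
    rule = METRICS[metric]["valid"]
    if rule == "any":
        return pd.Series(True, index=records.index)
    if rule == "n_valid_stim >= 1":
        return records["n_valid_stim"] >= 1
    if rule == "reliable":
        return records["reliable"].astype(bool)
    if rule == "band in bands":
        return records["reliable"].astype(bool) & records["band"].isin(_BAND_ORDER)
    raise AssertionError(rule)


def hexbin_aggregate(records: pd.DataFrame, metric: str,
                     hex_size_frac: float = 1 / 20) -> PhaseDiagramTable:
    """Median-aggregate a sweep table over a pointy-top hexagonal lattice.

    Each record falls in exactly one hexagon of the (w_e, w_i) plane, both
    axes normalized to [0, 1] over the span of the data before binning so
    the lattice is isotropic regardless of units; ``hex_size_frac`` is the
    hexagon center-to-vertex distance as a fraction of the axis span.
    Records invalid for the metric (per the rules in ``METRICS``) are
    excluded; the band metric uses the lower median over the ordinal band
    scale δ<θ<α<β<γ.
    """
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; one of {sorted(METRICS)}")
    df = (records[records["error"].fillna("") == ""].copy()
          if "error" in records else records.copy())
    if METRICS[metric]["per"] == "realization":
        df = df.drop_duplicates(
            subset=["N", "N_i", "p", "weight_point", "realization"])
    df = df[_valid_mask(df, metric)]

    we_lo, we_hi = float(records["w_e"].min()), float(records["w_e"].max())
    wi_lo, wi_hi = float(records["w_i"].min()), float(records["w_i"].max())
    we_span = (we_hi - we_lo) or 1.0
    wi_span = (wi_hi - wi_lo) or 1.0

    col = METRICS[metric]["column"]
    out_rows = []
    for (N_i, p), grp in df.groupby(["N_i", "p"], sort=True):
        x = (grp["w_e"].to_numpy() - we_lo) / we_span
        y = (grp["w_i"].to_numpy() - wi_lo) / wi_span
        q, r = _hex_assign(x, y, hex_size_frac)
        cells = pd.DataFrame({"q": q, "r": r, "val": grp[col].to_numpy()})
        for (qq, rr), cell in cells.groupby(["q", "r"]):
            vals = cell["val"]
            if metric == "band":
                codes = np.sort([_BAND_ORDER.index(b) for b in vals])
                value = _BAND_ORDER[codes[(len(codes) - 1) // 2]]
            else:
                value = float(np.median(vals.astype(float)))
            cx, cy = _hex_center(np.array([qq]), np.array([rr]), hex_size_frac)
            out_rows.append(dict(N_i=N_i, p=p, q=qq, r=rr,
                                 w_e=float(cx[0] * we_span + we_lo),
                                 w_i=float(cy[0] * wi_span + wi_lo),
                                 count=len(cell), value=value))
    cols = ["N_i", "p", "q", "r", "w_e", "w_i", "count", "value"]
    return PhaseDiagramTable(
        table=pd.DataFrame(out_rows, columns=cols), metric=metric,
        hex_size=(hex_size_frac, hex_size_frac),
        w_e_span=(we_lo, we_hi), w_i_span=(wi_lo, wi_hi))


_BAND_COLORS = {"delta": "#4d79ff", "theta": "#2db87d", "alpha": "#f2c14e",
                "beta": "#e2711d", "gamma": "#b3261e"}
_BAND_LABELS = {"delta": "δ", "theta": "θ", "alpha": "α",
                "beta": "β", "gamma": "γ"}


def render_phase_diagram(pdt: PhaseDiagramTable, path,
                         vmin: Optional[float] = None,
                         vmax: Optional[float] = None,
                         title: Optional[str] = None):
    """Draw the faceted hexbin figure: panels indexed by p (columns) and
    N_i (rows); empty hexagons are left white.  Numeric metrics use a
    sequential red scale (dark red = high); the band metric uses five
    categorical brain-wave colors.  Writes PNG or SVG per the path suffix.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import RegularPolygon

    tab = pdt.table
    if tab.empty:
        raise ValueError("phase-diagram table is empty; nothing to render")
    N_i_vals = sorted(tab["N_i"].unique())
    p_vals = sorted(tab["p"].unique())
    categorical = pdt.metric == "band"
    if not categorical:
        vals = tab["value"].astype(float)
        vmin = float(vals.min()) if vmin is None else vmin
        vmax = float(vals.max()) if vmax is None else vmax
        cmap = plt.get_cmap("Reds")
        norm = plt.Normalize(vmin, vmax if vmax > vmin else vmin + 1)

    fig, axes = plt.subplots(len(N_i_vals), len(p_vals),
                             figsize=(2.2 * len(p_vals), 2.2 * len(N_i_vals)),
                             squeeze=False)
    size = pdt.hex_size[0]
    for i, N_i in enumerate(N_i_vals):
        for j, p in enumerate(p_vals):
            ax = axes[i][j]
            sub = tab[(tab["N_i"] == N_i) & (tab["p"] == p)]
            for _, row in sub.iterrows():
                cx, cy = _hex_center(np.array([row["q"]]), np.array([row["r"]]), size)
                color = (_BAND_COLORS[row["value"]] if categorical
                         else cmap(norm(float(row["value"]))))
                ax.add_patch(RegularPolygon(
                    (cx[0], cy[0]), numVertices=6, radius=size,
                    orientation=0.0, facecolor=color, edgecolor="none"))
            ax.set_xlim(-size, 1 + size)
            ax.set_ylim(-size, 1 + size)
            ax.set_xticks([0, 1])
            ax.set_yticks([0, 1])
            ax.set_xticklabels([f"{pdt.w_e_span[0]:g}", f"{pdt.w_e_span[1]:g}"])
            ax.set_yticklabels([f"{pdt.w_i_span[0]:g}", f"{pdt.w_i_span[1]:g}"])
            if i == 0:
                ax.set_title(f"p={p:g}", fontsize=9)
            if j == 0:
                ax.set_ylabel(f"$N_i$={N_i}\n$w_i$", fontsize=8)
            if i == len(N_i_vals) - 1:
                ax.set_xlabel("$w_e$", fontsize=8)
    if categorical:
        import matplotlib.patches as mpatches
        handles = [mpatches.Patch(color=c, label=_BAND_LABELS[b])
                   for b, c in _BAND_COLORS.items()]
        fig.legend(handles=handles, loc="upper right", ncol=5, fontsize=8)
    else:
        sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
        fig.colorbar(sm, ax=axes, shrink=0.6, label=pdt.metric)
    fig.suptitle(title or f"phase diagram: {pdt.metric}")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
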