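"""Directed Erdős–Rényi networks of typed (excitatory/inhibitory) neurons.

Every ordered pair of distinct neurons is connected independently with
probability ``p``.  Excitatory neurons are regular spiking and project with a
single fixed weight ``w_e >= 0``; inhibitory neurons are fast spiking and
project with ``w_i <= 0``.  Which neurons are inhibitory is a uniformly random
index subset of size ``N_i``, controlled by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .neuron import NeuronParams, fast_spiking_params, regular_spiking_params

__all__ = ["NetworkConfig", "Network", "build_network", "network_summary",
           "write_edgelist", "read_edgelist"]


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of one network realization.

    N : total neuron count
    N_i : inhibitory count (0 < N_i < N)
    p : connection probability (sparseness)
    w_e : excitatory synaptic weight, >= 0, model current units
    w_i : inhibitory synaptic weight, <= 0
    seed : random-stream key for topology and type assignment
    symmetrize : if True, sample an undirected graph and mirror each edge
        (reciprocal directed pair); default is independent directed sampling
    """

    N: int
    N_i: int
    p: float
    w_e: float
    w_i: float
    seed: int = 0
    symmetrize: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.N_i < self.N:
            raise ValueError(
                f"N_i must satisfy 0 < N_i < N, got N_i={self.N_i}, N={self.N}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got p={self.p}")
        if self.w_e < 0:
            raise ValueError(f"w_e must be >= 0, got w_e={self.w_e}")
        if self.w_i > 0:
            raise ValueError(f"w_i must be <= 0, got w_i={self.w_i}")


@dataclass
class Network:
    """A realized network: weighted adjacency plus per-neuron phenotype.

    weights : CSR matrix, weights[i, j] is the synapse from presynaptic i to
        postsynaptic j (0 if absent); no self-edges.
    inhibitory : boolean array of length N, True where the neuron is
        inhibitory (fast spiking).
    """

    config: NetworkConfig
    weights: sp.csr_matrix
    inhibitory: np.ndarray
    params_excitatory: NeuronParams = field(default_factory=regular_spiking_params)
    params_inhibitory: NeuronParams = field(default_factory=fast_spiking_params)

    @property
    def N(self) -> int:
        return self.config.N

    @property
    def n_excitatory(self) -> int:
        return self.config.N - self.config.N_i

    @property
    def excitatory_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.inhibitory)


def build_network(cfg: NetworkConfig) -> Network:
    """Sample one Erdős–Rényi realization; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    inhib_idx = rng.choice(cfg.N, size=cfg.N_i, replace=False)
    inhibitory = np.zeros(cfg.N, dtype=bool)
    inhibitory[inhib_idx] = True

    adj = rng.random((cfg.N, cfg.N)) < cfg.p
    np.fill_diagonal(adj, False)
    if cfg.symmetrize:
        upper = np.triu(adj, k=1)
        adj = upper | upper.T

    row_weight = np.where(inhibitory, cfg.w_i, cfg.w_e)
    weights = sp.csr_matrix(adj * row_weight[:, None])
    return Network(config=cfg, weights=weights, inhibitory=inhibitory)


def network_summary(net: Network) -> dict:
    """Edge counts total and split by pre/post type, plus mean in-degree."""
    pre, post = net.weights.nonzero()
    pre_i = net.inhibitory[pre]
    post_i = net.inhibitory[post]
    counts = {
        "edges": int(len(pre)),
        "E->E": int(np.sum(~pre_i & ~post_i)),
        "E->I": int(np.sum(~pre_i & post_i)),
        "I->E": int(np.sum(pre_i & ~post_i)),
        "I->I": int(np.sum(pre_i & post_i)),
        "mean_in_degree": float(len(pre)) / net.N,
    }
    return counts


def write_edgelist(net: Network, path) -> None:
    """Plain-text edge list (presyn, postsyn, weight) with a config header."""
    cfg = net.config
    pre, post = net.weights.nonzero()
    w = np.asarray(net.weights[pre, post]).ravel()
    with open(path, "w") as fh:
        fh.write(f"# N={cfg.N} N_i={cfg.N_i} p={cfg.p} w_e={cfg.w_e} "
                 f"w_i={cfg.w_i} seed={cfg.seed} symmetrize={cfg.symmetrize}\n")
        fh.write("# inhibitory=" + ",".join(map(str, np.flatnonzero(net.inhibitory))) + "\n")
        for i, j, wij in zip(pre, post, w):
            fh.write(f"{i}\t{j}\t{wij:.17g}\n")


def read_edgelist(path) -> Network:
    """Inverse of :func:`write_edgelist`."""
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        inhib_line = fh.readline().lstrip("# ").strip()
        inhib_idx = [int(x) for x in inhib_line.split("=", 1)[1].split(",") if x]
        rows, cols, vals = [], [], []
        for line in fh:
            i, j, wij = line.split()
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(wij))
    cfg = NetworkConfig(
        N=int(meta["N"]), N_i=int(meta["N_i"]), p=float(meta["p"]),
        w_e=float(meta["w_e"]), w_i=float(meta["w_i"]), seed=int(meta["seed"]),
        symmetrize=meta.get("symmetrize", "False") == "True",
    )
    inhibitory = np.zeros(cfg.N, dtype=bool)
    inhibitory[inhib_idx] = True
    weights = sp.csr_matrix((vals, (rows, cols)), shape=(cfg.N, cfg.N))
    return Network(config=cfg, weights=weights, inhibitory=inhibitory)
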