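"""Graph metrics on binarized covariance networks.

Implements the three reported metric families on simple undirected graphs:

* clustering coefficient ``C = (1/n) sum_i 2 t_i / (k_i (k_i - 1))`` with
  ``C_i = 0`` for degree < 2, averaged over *all* nodes;
* characteristic pathlength in two conventions: the "as-printed" nodal
  inverse-distance form ``L_i = sum_{j != i} d_ij^{-1} / (n - 1)`` (an
  efficiency-like quantity, well defined on disconnected graphs, with
  unreachable pairs contributing 0) and the "classic" mean finite
  shortest-path length over reachable ordered pairs;
* normalized variants ``C_norm = C / C_rand`` and ``L_norm = L / L_rand``
  against the mean over an ensemble of random networks with the same number
  of nodes and edges (default 10 members), and the small-world index
  ``S = C_norm / L_norm``.

Distances are hop counts from breadth-first search. Ensemble models:
``"gnm"`` — uniform random simple graphs with identical n and m (the
default, matching a "same nodes and edges" null) — and ``"rewire"`` —
degree-preserving double-edge swaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._seeding import subseed
from .network import BinaryGraph

__all__ = [
    "clustering_coefficient",
    "characteristic_pathlength",
    "random_graph_gnm",
    "random_ensemble",
    "small_world",
    "GraphMetricSet",
]


def _as_adjacency(g) -> np.ndarray:
    adj = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)
    adj = adj.astype(bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric (undirected graph)")
    if adj.diagonal().any():
        raise ValueError("self-loops are not allowed")
    return adj


def clustering_coefficient(g) -> tuple[float, np.ndarray]:
    """Mean and nodal clustering coefficients.

    ``C_i = 2 t_i / (k_i (k_i - 1))`` where ``t_i`` counts triangles through
    node i; nodes of degree < 2 score 0 and remain in the denominator of the
    mean.
    """
    adj = _as_adjacency(g)
    a = adj.astype(np.float64)
    k = a.sum(axis=1)
    t = ((a @ a) * a).sum(axis=1) / 2.0  # triangles through each node
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(k >= 2, 2.0 * t / np.where(denom > 0, denom, 1.0), 0.0)
    return float(ci.mean()), ci


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop counts by breadth-first search (boolean matmul levels)."""
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    eye = np.eye(n, dtype=bool)
    reached = adj | eye
    frontier = adj.copy()
    level = 1
    while True:
        new = (frontier @ adj) & ~reached
        if not new.any():
            return d
        level += 1
        d[new] = level
        reached |= new
        frontier = new


def characteristic_pathlength(
    g, convention: str = "as-printed"
) -> tuple[float, np.ndarray]:
    """Characteristic pathlength and its nodal values.

    ``convention="as-printed"`` (default) uses the inverse-distance nodal
    form; ``"classic"`` averages finite shortest-path lengths over reachable
    ordered pairs (nodal value NaN for isolated nodes). An empty or
    single-node graph yields NaN.
    """
    adj = _as_adjacency(g)
    n = adj.shape[0]
    if n < 2:
        return float("nan"), np.full(n, np.nan)
    d = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    if convention == "as-printed":
        with np.errstate(divide="ignore"):
            inv = np.where(off & np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        li = inv.sum(axis=1) / (n - 1)
        return float(li.mean()), li
    if convention == "classic":
        finite = off & np.isfinite(d)
        counts = finite.sum(axis=1)
        with np.errstate(invalid="ignore"):
            li = np.where(counts > 0, np.where(finite, d, 0.0).sum(axis=1)
                          / np.maximum(counts, 1), np.nan)
        if not finite.any():
            return float("nan"), li
        return float(d[finite].mean()), li
    raise ValueError(f"unknown pathlength convention {convention!r}")


def random_graph_gnm(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random simple graph with exactly n nodes and m edges."""
    max_m = n * (n - 1) // 2
    if m > max_m:
        raise ValueError(f"m={m} exceeds n(n-1)/2={max_m}")
    ii, jj = np.triu_indices(n, 1)
    pick = rng.choice(max_m, size=m, replace=False)
    adj = np.zeros((n, n), dtype=bool)
    adj[ii[pick], jj[pick]] = True
    return adj | adj.T


def _rewired(adj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving randomization by double-edge swaps (10 m attempts)."""
    G = nx.from_numpy_array(adj)
    m = G.number_of_edges()
    if m >= 2:
        nx.double_edge_swap(
            G, nswap=10 * m, max_tries=200 * m,
            seed=int(rng.integers(2**31)),
        )
    return nx.to_numpy_array(G, dtype=bool, nodelist=range(adj.shape[0]))


def random_ensemble(
    g, n_rand: int = 10, model: str = "gnm", seed: int | None = None
) -> list[np.ndarray]:
    """Ensemble of random graphs matched to the input's size.

    Every member is simple and loop-free with exactly the input's n and m;
    the ``"rewire"`` model additionally preserves the degree sequence.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    adj = _as_adjacency(g)
    n = adj.shape[0]
    m = int(adj.sum()) // 2
    members = []
    for i in range(n_rand):
        rng = np.random.default_rng(subseed(seed if seed is not None else 0,
                                            "ensemble", model, i))
        if model == "gnm":
            members.append(random_graph_gnm(n, m, rng))
        elif model == "rewire":
            members.append(_rewired(adj, rng))
        else:
            raise ValueError(f"unknown ensemble model {model!r}")
    return members


@dataclass
class GraphMetricSet:
    """All reported metrics for one graph at one sparsity level."""

    sparsity: float | None
    n_nodes: int
    n_edges: int
    clustering: float
    clustering_nodal: np.ndarray
    pathlength: float
    pathlength_nodal: np.ndarray
    pathlength_classic: float
    clustering_rand: float
    pathlength_rand: float
    clustering_rand_se: float
    pathlength_rand_se: float
    clustering_norm: float
    pathlength_norm: float
    smallworld: float
    n_rand: int
    ensemble_model: str
    ensemble_seed: int | None
    convention: str = "as-printed"
    degrees: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "sparsity": self.sparsity,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "clustering": self.clustering,
            "pathlength": self.pathlength,
            "pathlength_classic": self.pathlength_classic,
            "clustering_rand": self.clustering_rand,
            "pathlength_rand": self.pathlength_rand,
            "clustering_rand_se": self.clustering_rand_se,
            "pathlength_rand_se": self.pathlength_rand_se,
            "clustering_norm": self.clustering_norm,
            "pathlength_norm": self.pathlength_norm,
            "smallworld": self.smallworld,
            "n_rand": self.n_rand,
            "ensemble_model": self.ensemble_model,
            "convention": self.convention,
        }


def small_world(
    g,
    n_rand: int = 10,
    model: str = "gnm",
    seed: int | None = None,
    convention: str = "as-printed",
    sparsity: float | None = None,
) -> GraphMetricSet:
    """Full metric set: C, L, random-ensemble normalizers, and S.

    ``C_rand`` and ``L_rand`` are simple means over the ensemble members
    (their standard errors are reported so normalization noise is visible).
    A zero normalizer leaves the corresponding ratio (and S) NaN.
    """
    adj = _as_adjacency(g)
    if sparsity is None and isinstance(g, BinaryGraph):
        sparsity = g.sparsity
    C, ci = clustering_coefficient(adj)
    L, li = characteristic_pathlength(adj, convention)
    L_classic, _ = characteristic_pathlength(adj, "classic")
    members = random_ensemble(adj, n_rand=n_rand, model=model, seed=seed)
    cr = np.array([clustering_coefficient(a)[0] for a in members])
    lr = np.array([characteristic_pathlength(a, convention)[0] for a in members])
    c_rand, l_rand = float(cr.mean()), float(lr.mean())
    c_norm = C / c_rand if c_rand > 0 else float("nan")
    l_norm = L / l_rand if l_rand > 0 else float("nan")
    s = (
        c_norm / l_norm
        if np.isfinite(c_norm) and np.isfinite(l_norm) and l_norm > 0
        else float("nan")
    )
    se = lambda x: float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return GraphMetricSet(
        sparsity=sparsity,
        n_nodes=adj.shape[0],
        n_edges=int(adj.sum()) // 2,
        clustering=C,
        clustering_nodal=ci,
        pathlength=L,
        pathlength_nodal=li,
        pathlength_classic=L_classic,
        clustering_rand=c_rand,
        pathlength_rand=l_rand,
        clustering_rand_se=se(cr),
        pathlength_rand_se=se(lr),
        clustering_norm=c_norm,
        pathlength_norm=l_norm,
        smallworld=s,
        n_rand=n_rand,
        ensemble_model=model,
        ensemble_seed=seed,
        convention=convention,
        degrees=adj.sum(axis=1),
    )
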