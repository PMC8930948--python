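"""Graph-theoretical metrics for directed weighted effective networks.

All quantities follow the conventions of the micro-scale culture-network
literature (as in the Brain Connectivity Toolbox): directed binary adjacency
``a_ij``, connection strengths ``S_ij`` in [0, 1], weighted distances over
edge lengths ``1/S_ij``, Fagiolo-style directed clustering, Leicht–Newman
directed modularity with Louvain optimization, and betweenness normalized by
``(N-1)(N-2)``.

Degenerate-input conventions (documented per function): silent source cells
give strength 0 with a warning; node pairs that are unreachable are excluded
(renormalized) from characteristic path lengths and contribute 0 to global
efficiency and betweenness; nodes whose degree admits no triangles contribute
clustering 0; a partition with a single module always has modularity 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .network import DegenerateNetworkWarning, EffectiveNetwork
from .raster import SpikeRaster

__all__ = [
    "DistanceMatrices",
    "NetworkMetrics",
    "ModuleStatistics",
    "firing_rate",
    "synchrony_kappa",
    "connection_strength",
    "strength_matrix",
    "connectivity_degree",
    "shortest_paths",
    "characteristic_path_length",
    "global_efficiency",
    "clustering_coefficient",
    "louvain_modules",
    "modularity_degree",
    "betweenness_centrality",
    "vulnerability",
    "network_strength",
    "module_statistics",
    "compute_all",
]


# ---------------------------------------------------------------------------
# raster-level measures


def firing_rate(raster: SpikeRaster) -> tuple[np.ndarray, float]:
    """Per-cell and mean firing rate in spikes per second (``s_i / duration``)."""
    if raster.duration_s <= 0:
        raise ValueError("duration must be positive")
    per_cell = raster.spike_counts() / raster.duration_s
    return per_cell, float(per_cell.mean())


def synchrony_kappa(raster: SpikeRaster) -> float:
    """Population synchrony as the mean pairwise Cohen's kappa.

    For each ordered cell pair, the two binary spike trains are treated as
    raters over the T frames: observed agreement
    ``p_o = (2 c_ij + T - s_i - s_j)/T`` (``c_ij`` = same-frame coincident
    spikes) is compared against the chance agreement
    ``p_e = (s_i s_j + (T - s_i)(T - s_j))/T^2``; the network value is the
    average of ``(p_o - p_e)/(1 - p_e)`` over the N(N-1) ordered pairs.
    Pairs with ``p_e = 1`` (both cells always silent or always active)
    contribute 0.
    """
    n, T = raster.n_cells, raster.n_frames
    if n < 2:
        raise ValueError("synchrony requires at least two cells")
    x = raster.spikes.astype(np.float64)
    s = x.sum(axis=1)
    c = x @ x.T
    p_o = (2.0 * c + T - s[:, None] - s[None, :]) / T
    p_e = (np.outer(s, s) + np.outer(T - s, T - s)) / T**2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(p_e < 1.0, (p_o - p_e) / (1.0 - p_e), 0.0)
    off = ~np.eye(n, dtype=bool)
    return float(kappa[off].mean())


def strength_matrix(raster: SpikeRaster, lag_frames: int = 1) -> np.ndarray:
    """All pairwise connection strengths ``S_ij = c_ij / s_i``.

    ``c_ij`` counts frames with a spike in source *i* at *t* and a spike in
    target *j* at *t + lag*; ``s_i`` counts source spikes in frames that have
    a following frame.  Rows of silent sources are 0.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    x = raster.spikes.astype(np.float64)
    a, b = x[:, :-lag_frames], x[:, lag_frames:]
    c = a @ b.T
    s = a.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        strength = np.where(s[:, None] > 0, c / np.where(s[:, None] > 0, s[:, None], 1.0), 0.0)
    return strength


def connection_strength(raster: SpikeRaster, i: int, j: int, lag_frames: int = 1) -> float:
    """Single-pair spike propagation probability ``S_ij = c_ij / s_i``."""
    x = raster.spikes
    a, b = x[i, :-lag_frames], x[j, lag_frames:]
    s_i = int(a.sum())
    if s_i == 0:
        warnings.warn(
            f"source cell {i} has no spikes; connection strength set to 0",
            DegenerateNetworkWarning,
            stacklevel=2,
        )
        return 0.0
    return float((a * b).sum() / s_i)


# ---------------------------------------------------------------------------
# structural measures


def connectivity_degree(net: EffectiveNetwork) -> float:
    """Fraction of realized directed connections out of all N(N-1) possible."""
    n = net.n_cells
    if n < 2:
        return 0.0
    return float(net.adjacency.sum() / (n * (n - 1)))


@dataclass
class DistanceMatrices:
    """Binary (link-count) and weighted shortest-path distances.

    Unreachable ordered pairs hold ``inf``; diagonals are 0.  Weighted
    distances accumulate edge lengths ``1/S_ij`` — a strong connection is a
    short link.
    """

    d_binary: np.ndarray
    d_weighted: np.ndarray


def shortest_paths(net: EffectiveNetwork) -> DistanceMatrices:
    """All-pairs shortest paths on links (BFS) and on edge lengths 1/S_ij.

    A predicted edge whose strength is exactly 0 carries infinite length and
    is traversable only in the binary matrix.
    """
    a = net.adjacency.astype(float)
    d_bin = _csgraph_shortest_path(csr_matrix(a), method="D", directed=True, unweighted=True)
    with np.errstate(divide="ignore"):
        lengths = np.where(net.weights > 0, 1.0 / np.where(net.weights > 0, net.weights, 1.0), 0.0)
    d_w = _csgraph_shortest_path(csr_matrix(lengths), method="D", directed=True)
    return DistanceMatrices(d_binary=d_bin, d_weighted=d_w)


def characteristic_path_length(
    dist: DistanceMatrices, mode: Literal["binary", "weighted"] = "binary"
) -> float:
    """Average shortest path length ``(1/N) sum_i mean_j d_ij``.

    Unreachable pairs are excluded and each node's inner average is
    renormalized over its reachable targets; nodes that reach no other node
    are excluded from the outer average.  Returns ``nan`` (with a warning)
    when no pair is reachable.
    """
    d = dist.d_binary if mode == "binary" else dist.d_weighted
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    terms = []
    for i in range(n):
        row = d[i, off[i]]
        finite = row[np.isfinite(row)]
        if finite.size:
            terms.append(finite.mean())
    if not terms:
        warnings.warn(
            "no reachable pairs: characteristic path length undefined",
            DegenerateNetworkWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(np.mean(terms))


def global_efficiency(dist: DistanceMatrices) -> float:
    """Mean inverse weighted distance, ``E^w``; unreachable pairs contribute 0."""
    d = dist.d_weighted
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def clustering_coefficient(
    net: EffectiveNetwork, mode: Literal["binary", "weighted"] = "binary"
) -> float:
    """Directed clustering coefficient, averaged over nodes.

    Per node the numerator counts all directed triangles through it over the
    eight edge-orientation combinations, ``(1/2) [(A + A^T)^3]_ii``; the
    denominator is the number of possible such triangles,
    ``(k_i^out + k_i^in)(k_i^out + k_i^in - 1) - 2 sum_j a_ij a_ji``.  In
    weighted mode the numerator replaces ``a_ij`` by ``S_ij^(1/3)`` (the
    Fagiolo convention) while the denominator stays binary.  Nodes with a
    zero denominator contribute 0.
    """
    a = net.adjacency.astype(float)
    w = a if mode == "binary" else np.cbrt(net.weights)
    s = w + w.T
    num = 0.5 * np.einsum("ij,jk,ki->i", s, s, s)
    k_tot = a.sum(axis=1) + a.sum(axis=0)
    recip = np.einsum("ij,ji->i", a, a)
    den = k_tot * (k_tot - 1.0) - 2.0 * recip
    c = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(c.mean())


def modularity_degree(net: EffectiveNetwork, module_labels: np.ndarray) -> float:
    """Directed modularity ``Q`` of a partition on the binary adjacency.

    ``Q = (1/l) sum_ij (a_ij - k_i^out k_j^in / l) delta(m_i, m_j)`` with
    ``l`` the number of links; the null term uses the directed
    (Leicht–Newman) configuration model.  A single all-in-one module gives
    ``Q = 0`` identically.
    """
    labels = np.asarray(module_labels)
    if labels.shape != (net.n_cells,):
        raise ValueError("module_labels must have one entry per cell")
    a = net.adjacency.astype(float)
    l = a.sum()
    if l == 0:
        raise ValueError("modularity is undefined for an edgeless network")
    k_out = a.sum(axis=1)
    k_in = a.sum(axis=0)
    same = labels[:, None] == labels[None, :]
    return float(((a - np.outer(k_out, k_in) / l) * same).sum() / l)


def _to_digraph(net: EffectiveNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(net.n_cells))
    g.add_edges_from(zip(*np.nonzero(net.adjacency)))
    return g


def louvain_modules(
    net: EffectiveNetwork, n_restarts: int = 100, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Louvain community detection under directed modularity.

    Runs ``n_restarts`` seeded Louvain passes (greedy node moves plus
    agglomeration) on the binary adjacency and returns the labelling with
    the highest directed modularity ``Q`` together with that ``Q``.  Labels
    are consecutive integers starting at 1.
    """
    if net.n_edges == 0:
        raise ValueError("community detection is undefined for an edgeless network")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    g = _to_digraph(net)
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    best_q = -np.inf
    best_labels: np.ndarray | None = None
    for s in rng_seeds:
        communities = nx.community.louvain_communities(g, weight=None, seed=int(s))
        labels = np.empty(net.n_cells, dtype=int)
        for m, members in enumerate(communities, start=1):
            labels[list(members)] = m
        q = modularity_degree(net, labels)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    assert best_labels is not None
    return best_labels, float(best_q)


def betweenness_centrality(net: EffectiveNetwork) -> tuple[np.ndarray, float]:
    """Normalized betweenness on binary shortest paths.

    ``b_i = (1/((N-1)(N-2))) sum_{h != j != i} rho_hj(i)/rho_hj`` where
    ``rho_hj`` counts shortest directed paths from h to j; unreachable pairs
    contribute 0.
    """
    g = _to_digraph(net)
    b = nx.betweenness_centrality(g, normalized=True)
    per_node = np.array([b[i] for i in range(net.n_cells)])
    return per_node, float(per_node.mean())


def vulnerability(net: EffectiveNetwork) -> tuple[np.ndarray, float]:
    """Relative global-efficiency loss after single-node removal.

    ``V(i) = (E^w - E^w(i)) / E^w`` with ``E^w(i)`` recomputed on the
    induced (N-1)-node network.  Raises when the intact network has zero
    efficiency.
    """
    e_full = global_efficiency(shortest_paths(net))
    if e_full == 0:
        raise ValueError("vulnerability is undefined when global efficiency is 0")
    n = net.n_cells
    v = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        sub = EffectiveNetwork(
            net.adjacency[np.ix_(keep, keep)], net.weights[np.ix_(keep, keep)]
        )
        v[i] = (e_full - global_efficiency(shortest_paths(sub))) / e_full
    return v, float(v.mean())


def network_strength(net: EffectiveNetwork) -> float:
    """Average connection strength over the network's predicted edges."""
    edges = net.adjacency == 1
    if not edges.any():
        warnings.warn(
            "network has no edges; network strength set to 0",
            DegenerateNetworkWarning,
            stacklevel=2,
        )
        return 0.0
    return float(net.weights[edges].mean())


# ---------------------------------------------------------------------------
# modules and aggregation


@dataclass
class ModuleStatistics:
    """Per-partition summaries: sizes, within-module degrees, firing rates."""

    n_modules: int
    sizes: np.ndarray
    within_in_degree: np.ndarray
    within_out_degree: np.ndarray
    firing_rate: np.ndarray | None = None


def module_statistics(
    net: EffectiveNetwork,
    module_labels: np.ndarray,
    raster: SpikeRaster | None = None,
) -> ModuleStatistics:
    """Module count, size histogram, within-module degrees, optional rates.

    Within-module in/out degree of a module is the mean, over its member
    cells, of the number of in/out edges to other members (a population of
    two-cell reciprocally connected modules shows means of exactly 1).
    """
    labels = np.asarray(module_labels)
    uniq = np.unique(labels)
    a = net.adjacency
    sizes, d_in, d_out, rates = [], [], [], []
    for m in uniq:
        members = np.nonzero(labels == m)[0]
        sizes.append(members.size)
        block = a[np.ix_(members, members)]
        d_in.append(block.sum(axis=0).mean())
        d_out.append(block.sum(axis=1).mean())
        if raster is not None:
            rates.append(
                raster.spike_counts()[members].mean() / raster.duration_s
            )
    return ModuleStatistics(
        n_modules=len(uniq),
        sizes=np.array(sizes),
        within_in_degree=np.array(d_in),
        within_out_degree=np.array(d_out),
        firing_rate=np.array(rates) if raster is not None else None,
    )


@dataclass
class NetworkMetrics:
    """One record of all per-network parameters (row unit for group stats)."""

    firing_rate_mean: float
    synchrony_kappa: float
    connectivity_degree: float
    network_strength: float
    cpl_binary: float
    cpl_weighted: float
    global_efficiency: float
    clustering_binary: float
    clustering_weighted: float
    modularity: float
    n_modules: int
    module_sizes: list[int] = field(default_factory=list)
    betweenness_mean: float = float("nan")
    vulnerability_mean: float = float("nan")

    #: scalar fields compared across treatment groups
    SCALAR_FIELDS = (
        "firing_rate_mean",
        "synchrony_kappa",
        "connectivity_degree",
        "network_strength",
        "cpl_binary",
        "cpl_weighted",
        "global_efficiency",
        "clustering_binary",
        "clustering_weighted",
        "modularity",
        "n_modules",
        "betweenness_mean",
        "vulnerability_mean",
    )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.SCALAR_FIELDS}
        d = {k: (float(v) if not isinstance(v, int) else v) for k, v in d.items()}
        d["n_modules"] = int(self.n_modules)
        d["module_sizes"] = [int(s) for s in self.module_sizes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkMetrics":
        return cls(**d)


def compute_all(
    net: EffectiveNetwork,
    raster: SpikeRaster | None = None,
    louvain_restarts: int = 100,
    seed: int = 0,
) -> NetworkMetrics:
    """Compute every network parameter for one recording.

    Raster-dependent fields (firing rate, synchrony) are ``nan`` when no
    raster is supplied (e.g. for random reference networks).  Deterministic
    given the Louvain seed.
    """
    if raster is not None and raster.n_cells != net.n_cells:
        raise ValueError("raster and network disagree on n_cells")
    dist = shortest_paths(net)
    if net.n_edges > 0:
        labels, q = louvain_modules(net, n_restarts=louvain_restarts, seed=seed)
        mod_stats = module_statistics(net, labels, raster)
        n_modules, sizes = mod_stats.n_modules, mod_stats.sizes.tolist()
    else:
        q, n_modules, sizes = float("nan"), 0, []
    e_w = global_efficiency(dist)
    if e_w > 0:
        _, vul_mean = vulnerability(net)
    else:
        vul_mean = float("nan")
    _, btw_mean = betweenness_centrality(net)
    return NetworkMetrics(
        firing_rate_mean=firing_rate(raster)[1] if raster is not None else float("nan"),
        synchrony_kappa=synchrony_kappa(raster) if raster is not None else float("nan"),
        connectivity_degree=connectivity_degree(net),
        network_strength=network_strength(net) if net.n_edges else 0.0,
        cpl_binary=characteristic_path_length(dist, "binary"),
        cpl_weighted=characteristic_path_length(dist, "weighted"),
        global_efficiency=e_w,
        clustering_binary=clustering_coefficient(net, "binary"),
        clustering_weighted=clustering_coefficient(net, "weighted"),
        modularity=q,
        n_modules=n_modules,
        module_sizes=sizes,
        betweenness_mean=btw_mean,
        vulnerability_mean=vul_mean,
    )
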