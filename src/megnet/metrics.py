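"""Topology metrics of the thresholded binary network.

Covers the full metric battery: mean clustering coefficient, global
efficiency, degree assortativity, Louvain module counts averaged over
repeated runs, rich-club extraction normalized against degree-preserving
random networks, hub identification (top 10% by degree), and per-edge
connection-frequency statistics over the canonical frequency bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from ._seeds import child_rng, child_seed
from .network import Edge, FunctionalNetwork

__all__ = [
    "DEFAULT_BANDS",
    "RichClubResult",
    "MetricsRecord",
    "clustering_coefficient",
    "global_efficiency",
    "assortativity",
    "louvain_modules",
    "rewire_preserving_degree",
    "rich_club_curve",
    "rich_club_analysis",
    "identify_hubs",
    "connection_frequency_stats",
]

# Canonical MEG band edges, Hz.  Half-open [low, high) except the top band,
# which is closed on the right so the 80 Hz analysis-band edge is counted.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}


def _as_graph(net: FunctionalNetwork | nx.Graph) -> nx.Graph:
    return net.to_networkx() if isinstance(net, FunctionalNetwork) else net


def clustering_coefficient(net: FunctionalNetwork | nx.Graph) -> float:
    """Mean per-node clustering, C_i = 2*T_i / (d_i (d_i - 1)), C_i = 0 if d_i < 2."""
    g = _as_graph(net)
    if g.number_of_nodes() < 3:
        raise ValueError("clustering needs at least 3 nodes")
    return float(nx.average_clustering(g, count_zeros=True))


def global_efficiency(net: FunctionalNetwork | nx.Graph) -> float:
    """Mean inverse shortest-path length over node pairs (0 for disconnected pairs)."""
    g = _as_graph(net)
    if g.number_of_nodes() < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    return float(nx.global_efficiency(g))


def assortativity(net: FunctionalNetwork | nx.Graph) -> float:
    """Newman's degree assortativity: Pearson r of endpoint degrees over edges.

    Each edge contributes both orientations.  On a regular graph (zero degree
    variance across endpoints) the correlation is undefined and NaN is
    returned.
    """
    g = _as_graph(net)
    if g.number_of_edges() < 2:
        raise ValueError("assortativity needs at least 2 edges")
    deg = dict(g.degree())
    x, y = [], []
    for u, v in g.edges():
        x += [deg[u], deg[v]]
        y += [deg[v], deg[u]]
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def louvain_modules(
    net: FunctionalNetwork | nx.Graph,
    n_runs: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean module count and mean modularity Q over repeated Louvain runs.

    Louvain is stochastic; the analysis is repeated ``n_runs`` times with
    independent seeds and the average number of modules (every node assigned;
    isolated nodes count as their own module) is reported together with the
    average modularity.  An edgeless graph has one module per node and Q = 0.
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        return float(n), 0.0
    counts = np.empty(n_runs)
    qs = np.empty(n_runs)
    for r in range(n_runs):
        comms = nx.community.louvain_communities(g, seed=child_seed(seed, "louvain", r))
        counts[r] = len(comms)
        qs[r] = nx.community.modularity(g, comms)
    return float(counts.mean()), float(qs.mean())


def _edge_array(g: nx.Graph) -> tuple[list, np.ndarray]:
    """Sorted node list and (m, 2) integer edge array of a graph."""
    nodes = sorted(g.nodes())
    idx = {n: k for k, n in enumerate(nodes)}
    edges = np.array(
        [(min(idx[u], idx[v]), max(idx[u], idx[v])) for u, v in g.edges()], dtype=np.int64
    ).reshape(-1, 2)
    return nodes, edges


def _rewire_edges(edges: np.ndarray, n: int, swaps_per_edge: int, rng: np.random.Generator) -> np.ndarray:
    """Double-edge swaps on an integer edge array; failed swaps skipped."""
    m = edges.shape[0]
    ed = edges.copy()
    present = {int(u) * n + int(v) for u, v in ed}
    attempts = swaps_per_edge * m
    picks = rng.integers(0, m, size=(attempts, 2))
    orients = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        a, b = picks[t]
        if a == b:
            continue
        u, v = int(ed[a, 0]), int(ed[a, 1])
        x, y = int(ed[b, 0]), int(ed[b, 1])
        if orients[t]:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        p, q = (u, x) if u < x else (x, u)
        r, s = (v, y) if v < y else (y, v)
        if p * n + q in present or r * n + s in present:
            continue
        present.discard(u * n + v)
        present.discard(x * n + y if x < y else y * n + x)
        present.add(p * n + q)
        present.add(r * n + s)
        ed[a] = (p, q)
        ed[b] = (r, s)
    return ed


def rewire_preserving_degree(
    net: FunctionalNetwork | nx.Graph,
    swaps_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> nx.Graph:
    """Maslov–Sneppen randomization: double-edge swaps preserving all degrees.

    Attempts ``swaps_per_edge * E`` swaps; a swap is skipped (not retried)
    when it would create a self-loop or a duplicate edge, so graphs with no
    valid swap (e.g. a star) come back unchanged.
    """
    g = _as_graph(net)
    m = g.number_of_edges()
    if m < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes, edges = _edge_array(g)
    rewired = _rewire_edges(edges, len(nodes), swaps_per_edge, rng)
    out = nx.Graph()
    out.add_nodes_from(nodes)
    out.add_edges_from((nodes[int(u)], nodes[int(v)]) for u, v in rewired)
    return out


def _phi_from_arrays(degrees: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    deg_sorted = np.sort(degrees)
    edge_min = np.sort(np.minimum(degrees[edges[:, 0]], degrees[edges[:, 1]]))
    max_deg = int(deg_sorted[-1]) if deg_sorted.size else 0
    ks, phis = [], []
    for k in range(0, max_deg):
        n_k = degrees.size - int(np.searchsorted(deg_sorted, k, side="right"))
        if n_k < 2:
            break
        e_k = edge_min.size - int(np.searchsorted(edge_min, k, side="right"))
        ks.append(k)
        phis.append(2.0 * e_k / (n_k * (n_k - 1)))
    if not ks:
        raise ValueError("no degree level with at least 2 nodes above it; no club definable")
    return np.asarray(ks), np.asarray(phis)


def rich_club_curve(net: FunctionalNetwork | nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    """Raw rich-club curve phi(k) = 2*E_{>k} / (N_{>k} (N_{>k} - 1)).

    ``E_{>k}`` and ``N_{>k}`` are the edge and node counts of the subgraph of
    nodes with degree strictly greater than k; evaluated for every k with at
    least two such nodes.
    """
    g = _as_graph(net)
    deg = dict(g.degree())
    if sum(1 for d in deg.values() if d >= 1) < 3:
        raise ValueError("rich-club analysis needs at least 3 nodes with degree >= 1")
    nodes, edges = _edge_array(g)
    degrees = np.array([deg[n] for n in nodes], dtype=np.int64)
    return _phi_from_arrays(degrees, edges)


@dataclass
class RichClubResult:
    """Rich club extracted at the degree level of maximal normalized phi.

    ``phi_norm(k) = phi(k) / mean(phi over degree-preserving random
    networks)``; the club level ``k_star`` is the argmax of ``phi_norm``
    (ties to the smallest k), the members are exactly the nodes with degree
    greater than ``k_star``, and the reported coefficient is the normalized
    value at that level.
    """

    ks: np.ndarray
    phi: np.ndarray
    phi_rand_mean: np.ndarray
    phi_norm: np.ndarray
    k_star: int
    members: list[str]
    n_nodes: int
    min_degree: int
    coefficient: float
    n_random: int

    def summary(self) -> dict:
        return {
            "k_star": self.k_star,
            "rich_club_nodes": self.n_nodes,
            "rich_club_min_degree": self.min_degree,
            "rich_club_coefficient": self.coefficient,
            "n_random": self.n_random,
        }


def rich_club_analysis(
    net: FunctionalNetwork | nx.Graph,
    n_random: int = 500,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> RichClubResult:
    """Rich-club extraction normalized against rewired random networks.

    phi(k) is normalized by its mean over ``n_random`` independently rewired
    degree-preserving networks (the degree sequence the curve conditions on
    is held fixed).  Levels where the random mean is zero while the real
    curve is positive normalize to +inf (an infinitely differentiated club);
    levels where both are zero are not selectable.
    """
    g = _as_graph(net)
    ks, phi = rich_club_curve(g)
    nodes, edges = _edge_array(g)
    deg_map = dict(g.degree())
    degrees = np.array([deg_map[n] for n in nodes], dtype=np.int64)
    acc = np.zeros_like(phi)
    for r in range(n_random):
        rewired = _rewire_edges(edges, len(nodes), swaps_per_edge, child_rng(seed, "rewire", r))
        _, phi_r = _phi_from_arrays(degrees, rewired)  # same degree sequence -> same k support
        acc += phi_r
    phi_rand_mean = acc / n_random
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_norm = phi / phi_rand_mean
    phi_norm = np.where((phi_rand_mean == 0) & (phi == 0), np.nan, phi_norm)
    if np.all(np.isnan(phi_norm)):
        raise ValueError("normalized rich-club curve is undefined at every level")
    k_idx = int(np.nanargmax(phi_norm))  # first index on ties -> smallest k
    k_star = int(ks[k_idx])
    deg = dict(g.degree())
    members = sorted(n for n, d in deg.items() if d > k_star)
    return RichClubResult(
        ks=ks,
        phi=phi,
        phi_rand_mean=phi_rand_mean,
        phi_norm=phi_norm,
        k_star=k_star,
        members=members,
        n_nodes=len(members),
        min_degree=int(min(deg[n] for n in members)),
        coefficient=float(phi_norm[k_idx]),
        n_random=n_random,
    )


def identify_hubs(net: FunctionalNetwork | nx.Graph, fraction: float = 0.10) -> list[str]:
    """The top ``max(1, floor(fraction*N))`` nodes by degree (ties by label)."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("empty graph")
    n_hubs = max(1, math.floor(fraction * n))
    ranked = sorted(g.degree(), key=lambda t: (-t[1], t[0]))
    return [lab for lab, _ in ranked[:n_hubs]]


def connection_frequency_stats(
    edges: Iterable[Edge] | Sequence[float],
    bands: dict[str, tuple[float, float]] | None = None,
) -> tuple[float, dict[str, int]]:
    """Mean connection frequency and per-band connection counts.

    Accepts annotated edges or bare frequencies.  Bands are half-open
    [low, high); the highest band additionally includes its right edge.
    With zero edges the mean is NaN (flag) and every count is zero.
    """
    bands = bands or DEFAULT_BANDS
    freqs = np.asarray(
        [e.f_star if isinstance(e, Edge) else float(e) for e in edges], float
    )
    counts = {name: 0 for name in bands}
    top = max(hi for _, hi in bands.values())
    for f in freqs:
        for name, (lo, hi) in bands.items():
            if lo <= f < hi or (f == hi == top):
                counts[name] += 1
                break
    mean_f = float(freqs.mean()) if freqs.size else float("nan")
    return mean_f, counts


@dataclass
class MetricsRecord:
    """The full per-subject/timepoint metric battery."""

    subject_id: str
    timepoint: str
    n_nodes: int
    n_edges: int
    achieved_degree: float
    clustering_coefficient: float
    global_efficiency: float
    assortativity: float
    rich_club: RichClubResult = field(repr=False)
    n_modules_mean: float = float("nan")
    modularity_mean: float = float("nan")
    mean_connection_frequency: float = float("nan")
    band_counts: dict[str, int] = field(default_factory=dict)
    hubs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "timepoint": self.timepoint,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "achieved_degree": self.achieved_degree,
            "clustering_coefficient": self.clustering_coefficient,
            "global_efficiency": self.global_efficiency,
            "assortativity": self.assortativity,
            "n_modules_mean": self.n_modules_mean,
            "modularity_mean": self.modularity_mean,
            "mean_connection_frequency": self.mean_connection_frequency,
            "band_counts": dict(self.band_counts),
            "hubs": list(self.hubs),
            "rich_club": {
                **self.rich_club.summary(),
                "members": list(self.rich_club.members),
                "ks": self.rich_club.ks.tolist(),
                "phi": self.rich_club.phi.tolist(),
                "phi_rand_mean": self.rich_club.phi_rand_mean.tolist(),
                "phi_norm": [
                    None if np.isnan(v) else float(v) for v in self.rich_club.phi_norm
                ],
            },
        }
        return d
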