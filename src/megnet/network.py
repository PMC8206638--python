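"""Graph construction under the S-exponent density criterion.

Gated edge candidates are turned into a simple undirected graph whose
density satisfies ``S = log(N)/log(K)`` for the configured exponent
(default S = 2.5): the target average degree is ``K = N**(1/S)`` and the
target edge count ``E = round(N*K/2)``.  The E strongest candidates by gate
effect size z are retained; if the noise gate already leaves fewer than E
candidates, all of them are kept and the achieved degree recorded (the gate
is a noise floor and is never relaxed to reach the target density).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np

from .connectivity import EdgeCandidate

__all__ = ["Edge", "FunctionalNetwork", "TargetDegree", "target_degree", "threshold_network"]


@dataclass(frozen=True)
class Edge:
    """Undirected edge annotated with its connection frequency and effect size."""

    i: str
    j: str
    f_star: float
    z_max: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-loops are not allowed")
        if self.i > self.j:
            raise ValueError("edges are stored with i < j in label order")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.i, self.j)


@dataclass
class FunctionalNetwork:
    """Simple undirected graph with per-edge frequency (Hz) and effect size z.

    Downstream metrics treat the graph as binary; ``f_star``/``z_max`` are
    annotations only.
    """

    node_labels: list[str]
    edges: list[Edge]
    sparse_warning: bool = False  # set when the gate left fewer edges than S requires
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_labels = list(self.node_labels)
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")
        nodes = set(self.node_labels)
        seen = set()
        for e in self.edges:
            if e.i not in nodes or e.j not in nodes:
                raise ValueError(f"edge {e.pair} references an unknown node")
            if e.pair in seen:
                raise ValueError(f"duplicate edge {e.pair}")
            seen.add(e.pair)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def average_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes if self.n_nodes else 0.0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        g.add_edges_from(
            (e.i, e.j, {"f_star": e.f_star, "z_max": e.z_max}) for e in self.edges
        )
        return g

    def adjacency_matrix(self) -> np.ndarray:
        idx = {lab: k for k, lab in enumerate(self.node_labels)}
        a = np.zeros((self.n_nodes, self.n_nodes))
        for e in self.edges:
            a[idx[e.i], idx[e.j]] = a[idx[e.j], idx[e.i]] = 1.0
        return a


class TargetDegree(NamedTuple):
    k: float
    n_edges: int


def target_degree(n_nodes: int, s: float = 2.5) -> TargetDegree:
    """Average degree K and edge count E implied by S = log(N)/log(K).

    ``K = N**(1/S)`` and ``E = round(N*K/2)`` (half-up rounding, documented;
    the direction is immaterial at the 41-node scale where N*K/2 = 90.55).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if s <= 0:
        raise ValueError("S exponent must be positive")
    k = float(n_nodes) ** (1.0 / s)
    n_edges = int(np.floor(n_nodes * k / 2.0 + 0.5))
    return TargetDegree(k=k, n_edges=n_edges)


def threshold_network(
    candidates: Iterable[EdgeCandidate],
    node_labels: list[str],
    s: float = 2.5,
) -> FunctionalNetwork:
    """Retain the E strongest gated candidates (E from :func:`target_degree`).

    Candidates that failed the noise gate are discarded first.  The survivors
    are ranked by descending z; ties at the E-th rank are broken by lower
    connection frequency, then label order, so the result is deterministic.
    If fewer than E candidates passed the gate, all are kept and the network
    is marked sparse.  Zero gated candidates yield an empty-edge network with
    a warning flag rather than an error.
    """
    node_labels = list(node_labels)
    gated = [c for c in candidates if c.connected]
    e_target = target_degree(len(node_labels), s).n_edges
    gated.sort(key=lambda c: (-c.z_max, c.f_star, c.pair))
    kept = gated[:e_target]
    edges = [Edge(i=c.pair[0], j=c.pair[1], f_star=c.f_star, z_max=c.z_max) for c in kept]
    return FunctionalNetwork(
        node_labels=node_labels,
        edges=edges,
        sparse_warning=len(gated) < e_target,
        meta={
            "s_exponent": s,
            "target_edges": e_target,
            "gated_candidates": len(gated),
            "achieved_degree": 2.0 * len(edges) / len(node_labels),
        },
    )
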