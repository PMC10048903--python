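"""Molecular Complex Detection (MCODE): dense-subnetwork mining.

Seeded-growth complex detection in three stages:

1. *Vertex weighting.*  Each vertex v is weighted by the density of the
   highest k-core of its closed neighborhood (v plus its neighbors):
   weight(v) = k_max * density(k_max-core).  A vertex inside an n-clique gets
   weight n - 1; a leaf gets 1 (its closed neighborhood is a single edge);
   an isolated vertex gets 0.

2. *Complex prediction.*  Seeds are consumed in weight-descending order
   (ties by node id).  From each unassigned seed, breadth-first expansion
   admits neighbors whose weight is at least seed_weight * (1 - vwp), where
   vwp is the node-score cutoff, up to ``max_depth`` hops from the seed.
   A node joins at most one complex.

3. *Post-processing.*  Complexes without a ``k_core_filter``-core are
   discarded; optional *fluff* admits outside neighbors whose closed-
   neighborhood density exceeds a cutoff; *haircut* iteratively strips
   degree-1 members.

Each surviving complex is scored density * |members| (density without
self-loops: 2E / (n (n-1))) and complexes are ranked by score descending.
Defaults mirror the standard tool: node score cutoff 0.2, haircut on, fluff
off with density cutoff 0.1, k-core filter 2, max depth 100.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

__all__ = ["MCODEParams", "Complex", "vertex_weights", "cluster_score", "predict_complexes"]


@dataclass(frozen=True)
class MCODEParams:
    node_score_cutoff: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1
    k_core_filter: int = 2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.node_score_cutoff < 1:
            raise ValueError(f"node_score_cutoff must be in [0, 1), got {self.node_score_cutoff}")
        if not 0 <= self.fluff_density_cutoff <= 1:
            raise ValueError(
                f"fluff_density_cutoff must be in [0, 1], got {self.fluff_density_cutoff}"
            )
        if self.k_core_filter < 0:
            raise ValueError(f"k_core_filter must be >= 0, got {self.k_core_filter}")
        if self.max_depth < 1:
            raise ValueError(f"max_depth must be >= 1, got {self.max_depth}")


@dataclass(frozen=True)
class Complex:
    """A detected dense subnetwork: members, induced edge count, score, 1-based rank."""

    members: frozenset
    edge_count: int
    score: float
    rank: int

    def __len__(self) -> int:
        return len(self.members)


def _closed_neighborhood_density(net: nx.Graph, v) -> float:
    sub = net.subgraph(list(net[v]) + [v])
    n = sub.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * sub.number_of_edges() / (n * (n - 1))


def vertex_weights(net: nx.Graph) -> dict:
    """Local-neighborhood-density weight of every vertex.

    weight(v) = k_max * density of the k_max-core of v's closed neighborhood,
    where k_max is the highest core number occurring there.  Isolated vertices
    weigh 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    weights = {}
    for v in net:
        sub = net.subgraph(list(net[v]) + [v])
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        cores = nx.core_number(sub)
        k_max = max(cores.values())
        core = sub.subgraph([u for u, c in cores.items() if c >= k_max])
        n = core.number_of_nodes()
        density = 2.0 * core.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
        weights[v] = k_max * density
    return weights


def cluster_score(members, edge_count: int) -> float:
    """MCODE complex score: density times node count.

    ``members`` may be the member collection or the member count.  With n
    members and E induced edges the score is n * 2E / (n (n-1)) = 2E / (n-1);
    an n-clique scores n.
    """
    n = members if isinstance(members, int) else len(members)
    if n < 2:
        raise ValueError(f"a complex needs >= 2 members, got {n}")
    if edge_count < 0:
        raise ValueError("edge_count must be non-negative")
    return 2.0 * edge_count / (n * (n - 1)) * n


def _haircut(sub: nx.Graph) -> nx.Graph:
    sub = nx.Graph(sub)
    while True:
        leaves = [v for v, d in sub.degree() if d <= 1]
        if not leaves:
            return sub
        sub.remove_nodes_from(leaves)


def predict_complexes(net: nx.Graph, params: MCODEParams | None = None) -> list[Complex]:
    """Detect dense complexes, ranked by score descending.

    Deterministic: seeds in weight-descending order with id tie-break, final
    ranking by (score descending, member ids).  With default parameters the
    returned complexes are pairwise disjoint; fluff may introduce overlap.
    """
    params = params or MCODEParams()
    weights = vertex_weights(net)
    threshold_frac = 1.0 - params.node_score_cutoff
    assigned: set = set()
    raw_members: list[set] = []

    for seed in sorted(net, key=lambda v: (-weights[v], str(v))):
        if seed in assigned or weights[seed] <= 0:
            continue
        cutoff = weights[seed] * threshold_frac
        members = {seed}
        queue = deque([(seed, 0)])
        while queue:
            v, depth = queue.popleft()
            if depth >= params.max_depth:
                continue
            for u in net[v]:
                if u in members or u in assigned:
                    continue
                if weights[u] >= cutoff:
                    members.add(u)
                    queue.append((u, depth + 1))
        assigned |= members
        raw_members.append(members)

    complexes = []
    for members in raw_members:
        sub = nx.Graph(net.subgraph(members))
        # k-core filter: the complex must contain a k_core_filter-core
        if params.k_core_filter > 0 and nx.k_core(sub, params.k_core_filter).number_of_nodes() == 0:
            continue
        if params.fluff:
            extras = {
                u
                for v in sub
                for u in net[v]
                if u not in sub and _closed_neighborhood_density(net, u) > params.fluff_density_cutoff
            }
            sub = nx.Graph(net.subgraph(set(sub) | extras))
        if params.haircut:
            sub = _haircut(sub)
        if sub.number_of_nodes() < 2:
            continue
        complexes.append((frozenset(sub), sub.number_of_edges()))

    complexes.sort(key=lambda me: (-cluster_score(me[0], me[1]), sorted(str(v) for v in me[0])))
    return [
        Complex(members=m, edge_count=e, score=cluster_score(m, e), rank=i)
        for i, (m, e) in enumerate(complexes, start=1)
    ]
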