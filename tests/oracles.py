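"""Independent brute-force oracles used to validate the fast implementations.

Everything here works from first principles on raw adjacency (explicit
simple-path enumeration, dense eigendecomposition, combinatorial tail sums)
and deliberately avoids the library code paths under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _adjacency(graph) -> dict:
    adj: dict = {v: set() for v in graph.nodes()}
    for a, b in graph.edges():
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _all_simple_paths(adj: dict, source, target) -> list:
    """Every simple path from source to target, by explicit DFS."""
    paths, stack = [], [(source, [source])]
    while stack:
        v, path = stack.pop()
        if v == target:
            paths.append(path)
            continue
        for u in adj[v]:
            if u not in path:
                stack.append((u, path + [u]))
    return paths


def brute_betweenness(graph) -> dict:
    """Normalized betweenness via enumeration of all shortest paths per pair."""
    adj = _adjacency(graph)
    nodes = list(adj)
    n = len(nodes)
    scores = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == d]
        for p in geodesics:
            for v in p[1:-1]:
                scores[v] += 1.0 / len(geodesics)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: (scores[v] / norm if norm else 0.0) for v in nodes}


def brute_closeness(graph) -> dict:
    """Per-component closeness (reachable - 1) / sum of BFS distances."""
    adj = _adjacency(graph)
    result = {}
    for s in adj:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for v in frontier:
                for u in adj[v]:
                    if u not in dist:
                        dist[u] = dist[v] + 1
                        nxt.append(u)
            frontier = nxt
        total = sum(dist.values())
        result[s] = (len(dist) - 1) / total if total else 0.0
    return result


def brute_eigenvector(graph) -> dict:
    """Principal eigenvector of the adjacency matrix by dense symmetric eig."""
    nodes = list(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for a, b in graph.edges():
        A[index[a], index[b]] = A[index[b], index[a]] = 1.0
    _, vecs = np.linalg.eigh(A)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    return dict(zip(nodes, v))


def brute_ffls(regulatory_net) -> set:
    """All (tf, mirna, gene, s1, s2, s3) tuples by an O(n^3) triple scan."""
    by_layer: dict = {}
    for e in regulatory_net.edges:
        by_layer.setdefault(e.layer, {})[(e.source, e.target)] = e.sign
    tf_mirna = by_layer.get("tf_mirna", {})
    mirna_gene = by_layer.get("mirna_gene", {})
    tf_gene = by_layer.get("tf_gene", {})
    tfs = {s for s, _ in tf_mirna} | {s for s, _ in tf_gene}
    mirnas = {t for _, t in tf_mirna} | {s for s, _ in mirna_gene}
    genes = {t for _, t in mirna_gene} | {t for _, t in tf_gene}
    found = set()
    for tf in tfs:
        for mir in mirnas:
            for gene in genes:
                if gene == tf:
                    continue
                s1 = tf_mirna.get((tf, mir))
                s2 = mirna_gene.get((mir, gene))
                s3 = tf_gene.get((tf, gene))
                if None not in (s1, s2, s3):
                    found.add((tf, mir, gene, s1, s2, s3))
    return found


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by explicit summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total
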