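"""Seeded generators for every input regime the pipeline consumes.

Four generators cover the study conditions the analysis assumes, so each
stage is testable without any database export:

* :func:`gen_scale_free` — preferential attachment, the heavy-tailed degree
  regime behind power-law degree-distribution fits and disassortativity.
* :func:`gen_hierarchical` — the deterministic replica construction
  (a complete base module copied ``base - 1`` times per level, replica
  periphery wired to the central hub), which provably shows the hierarchical
  signature C(k) ~ k^-1.
* :func:`gen_planted_clusters` — sparse background with embedded cliques plus
  ground-truth membership, the recovery benchmark for complex detection.
* :func:`gen_signed_regnet` — random signed tripartite regulatory layers with
  optionally planted feed-forward loops of chosen types, plus the brute-force
  ground-truth motif list.

All generators are deterministic given ``seed``; planted structure is always
returned alongside the data.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from .netio import SignedEdge
from .regnet import (
    FFL_TYPE_TABLE,
    FFLMotif,
    SignedRegulatoryNetwork,
    assemble,
    classify_ffl,
)

__all__ = [
    "gen_scale_free",
    "gen_hierarchical",
    "gen_planted_clusters",
    "gen_signed_regnet",
    "degree_preserving_rewire",
]


def gen_scale_free(n: int, m: int, seed: int) -> nx.Graph:
    """Barabasi-Albert preferential-attachment graph: connected, heavy-tailed.

    Requires m <= n - 2 so at least one preferential-attachment step occurs
    (at m = n - 1 the construction degenerates to its seed star).
    """
    if not 1 <= m <= n - 2:
        raise ValueError(f"need 1 <= m <= n - 2, got m={m}, n={n}")
    graph = nx.barabasi_albert_graph(n, m, seed=seed)
    return nx.relabel_nodes(graph, {v: f"N{v}" for v in graph})


def gen_hierarchical(levels: int, base: int = 5, seed: int = 0, copies: int = 1) -> nx.Graph:
    """Deterministic hierarchical-modular graph of ``copies * base**levels`` nodes.

    Level 1 is a complete module of ``base`` nodes with node 0 as the hub.
    At each further level the current graph is replicated ``base - 1`` times
    and every peripheral node of the replicas (non-hub nodes of the base
    modules at level 1, the replicas' own peripheries afterwards) is wired to
    the central hub.  Clustering then falls roughly as 1/k with degree — the
    hierarchical signature — while the degree distribution stays heavy-tailed.

    ``copies`` places that many disjoint hierarchical blocks side by side.
    One block's central hub sits far above the structural cutoff
    sqrt(N <k>), so a degree-preserving randomization of a *single* block
    shows an artifactual clustering-degree decay; an ensemble of ~10 blocks
    keeps every degree below the cutoff, making the rewired null flat and the
    hierarchy test meaningful.  ``seed`` is accepted for interface symmetry;
    the construction is deterministic.
    """
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    if base < 4:
        raise ValueError(f"base must be >= 4, got {base}")
    if copies < 1:
        raise ValueError(f"copies must be >= 1, got {copies}")
    graph = nx.complete_graph(base)
    periphery = list(range(1, base))
    for _ in range(1, levels):
        n = graph.number_of_nodes()
        block = nx.Graph(graph)
        new_periphery = []
        for copy in range(1, base):
            offset = copy * n
            graph.update(nx.relabel_nodes(block, {v: v + offset for v in block}))
            new_periphery.extend(p + offset for p in periphery)
        graph.add_edges_from((p, 0) for p in new_periphery)
        periphery = new_periphery
    if copies > 1:
        n = graph.number_of_nodes()
        block = nx.Graph(graph)
        for copy in range(1, copies):
            offset = copy * n
            graph.update(nx.relabel_nodes(block, {v: v + offset for v in block}))
    return nx.relabel_nodes(graph, {v: f"H{v}" for v in graph})


def degree_preserving_rewire(net: nx.Graph, seed: int, nswap_per_edge: int = 10) -> nx.Graph:
    """Degree-matched null model by repeated double edge swaps."""
    rewired = nx.Graph(net)
    nswap = nswap_per_edge * rewired.number_of_edges()
    nx.double_edge_swap(rewired, nswap=nswap, max_tries=100 * nswap, seed=seed)
    return rewired


def gen_planted_clusters(
    n_background: int,
    p_background: float,
    clique_sizes: list[int],
    attach_prob: float = 0.02,
    seed: int = 0,
) -> tuple[nx.Graph, list[set]]:
    """Sparse Erdos-Renyi background with embedded cliques; returns ground truth.

    Each planted clique gets its own fresh nodes (``Q{i}_{j}``) and every
    clique node is attached to each background node independently with
    probability ``attach_prob``.  Returns ``(graph, memberships)`` where
    ``memberships[i]`` is the node set of planted clique i.
    """
    if not 0 <= p_background <= 1 or not 0 <= attach_prob <= 1:
        raise ValueError("probabilities must be in [0, 1]")
    if any(s < 4 for s in clique_sizes):
        raise ValueError(f"clique sizes must be >= 4, got {clique_sizes}")
    if n_background < 1:
        raise ValueError("n_background must be >= 1")
    rng = np.random.default_rng(seed)
    graph = nx.gnp_random_graph(n_background, p_background, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(graph, {v: f"B{v}" for v in graph})
    background_nodes = sorted(graph)
    memberships: list[set] = []
    for i, size in enumerate(clique_sizes):
        members = {f"Q{i}_{j}" for j in range(size)}
        graph.add_edges_from(itertools.combinations(sorted(members), 2))
        for v in sorted(members):
            for b in background_nodes:
                if rng.random() < attach_prob:
                    graph.add_edge(v, b)
        memberships.append(members)
    return graph, memberships


_INV_TYPE_TABLE = {label: signs for signs, label in FFL_TYPE_TABLE.items()}


def _brute_force_ffls(net: SignedRegulatoryNetwork) -> list[FFLMotif]:
    """Independent O(n^3) scan over all role-compatible triples."""
    motifs = []
    for tf in sorted(net.nodes_with_role("TF")):
        for mirna in sorted(net.nodes_with_role("miRNA")):
            for gene in sorted(net.nodes_with_role("gene")):
                if gene == tf:
                    continue
                s1 = net.sign(tf, mirna, "tf_mirna")
                s2 = net.sign(mirna, gene, "mirna_gene")
                s3 = net.sign(tf, gene, "tf_gene")
                if None in (s1, s2, s3):
                    continue
                coherence, label = classify_ffl(s1, s2, s3)
                motifs.append(FFLMotif(tf, mirna, gene, s1, s2, s3, coherence, label))
    return motifs


def gen_signed_regnet(
    n_tf: int,
    n_mirna: int,
    n_gene: int,
    edge_probs: dict[str, float] | None = None,
    activation_prob: float = 0.5,
    planted_ffls: list[str] | None = None,
    seed: int = 0,
    mirna_repressive: bool = True,
) -> tuple[SignedRegulatoryNetwork, list[FFLMotif]]:
    """Random signed tripartite regulatory network with planted FFLs.

    ``edge_probs`` gives the Bernoulli edge probability per layer (keys among
    ``tf_mirna``, ``mirna_gene``, ``tf_gene``, ``gene_mirna``; missing layers
    default to 0).  TF-borne edge signs are +1 with ``activation_prob``;
    miRNA->gene edges are fixed at -1 unless ``mirna_repressive`` is False.
    Each requested FFL type label (C1-C4/I1-I4) is planted on fresh nodes.
    Returns the network plus the full ground-truth motif list (planted and
    incidental), recomputed by an independent brute-force triple scan.
    """
    edge_probs = dict(edge_probs or {})
    unknown = set(edge_probs) - {"tf_mirna", "mirna_gene", "tf_gene", "gene_mirna"}
    if unknown:
        raise ValueError(f"unknown layers in edge_probs: {sorted(unknown)}")
    if any(not 0 <= p <= 1 for p in edge_probs.values()) or not 0 <= activation_prob <= 1:
        raise ValueError("probabilities must be in [0, 1]")
    for label in planted_ffls or []:
        if label not in _INV_TYPE_TABLE:
            raise ValueError(f"unknown FFL type label {label!r}")
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i}" for i in range(n_tf)]
    mirnas = [f"miR-{i}" for i in range(n_mirna)]
    genes = [f"G{i}" for i in range(n_gene)]

    def tf_sign() -> int:
        return 1 if rng.random() < activation_prob else -1

    def mirna_sign() -> int:
        return -1 if mirna_repressive else tf_sign()

    edges: list[SignedEdge] = []
    for layer, sources, targets, sign_fn in (
        ("tf_mirna", tfs, mirnas, tf_sign),
        ("mirna_gene", mirnas, genes, mirna_sign),
        ("tf_gene", tfs, genes, tf_sign),
        ("gene_mirna", genes, mirnas, tf_sign),
    ):
        p = edge_probs.get(layer, 0.0)
        for s in sources:
            for t in targets:
                if rng.random() < p:
                    edges.append(SignedEdge(s, t, sign_fn(), layer))

    for i, label in enumerate(planted_ffls or []):
        s1, s2, s3 = _INV_TYPE_TABLE[label]
        tf, mirna, gene = f"pTF{i}", f"pmiR-{i}", f"pG{i}"
        edges.append(SignedEdge(tf, mirna, s1, "tf_mirna"))
        edges.append(SignedEdge(mirna, gene, s2, "mirna_gene"))
        edges.append(SignedEdge(tf, gene, s3, "tf_gene"))

    net = assemble(edges)
    return net, _brute_force_ffls(net)
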