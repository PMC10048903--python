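"""Signed TF-miRNA-gene regulatory networks and feed-forward-loop motifs.

The network is a directed signed tripartite graph over three node roles
(TF, miRNA, gene) with four edge layers: TF->gene and TF->miRNA
(transcriptional), miRNA->gene (post-transcriptional repression or, rarely,
activation) and gene->miRNA (a gene product acting back on a miRNA, which is
how feedback loops arise).  A node may be both TF and gene — e.g. a hub gene
that itself transactivates a miRNA — but the miRNA role is exclusive.

A feed-forward loop (FFL) is a triple (TF, miRNA, gene) carrying all three of
TF->miRNA (sign s1), miRNA->gene (s2) and TF->gene (s3).  The motif is
*coherent* when the direct sign equals the product of the indirect path,
s3 = s1 * s2, and *incoherent* otherwise; the eight sign patterns map onto
the standard C1-C4 / I1-I4 nomenclature.  A gene-miRNA feedback loop is a
reciprocal pair gene->miRNA / miRNA->gene whose loop sign is the product of
the two edge signs (negative feedback when the signs differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .netio import LAYERS, SignedEdge

__all__ = [
    "FFL_TYPE_TABLE",
    "FFLMotif",
    "FeedbackLoop",
    "SignedRegulatoryNetwork",
    "consensus_targets",
    "assemble",
    "classify_ffl",
    "enumerate_ffls",
    "enumerate_feedback_loops",
]

#: (sign TF->miRNA, sign miRNA->gene, sign TF->gene) -> standard FFL type label
FFL_TYPE_TABLE = {
    (1, 1, 1): "C1",
    (-1, 1, -1): "C2",
    (1, -1, -1): "C3",
    (-1, -1, 1): "C4",
    (1, -1, 1): "I1",
    (-1, 1, 1): "I2",
    (1, 1, -1): "I3",
    (-1, -1, -1): "I4",
}

_ALLOWED_ROLE_SETS = ({"TF"}, {"gene"}, {"miRNA"}, {"TF", "gene"})


@dataclass(frozen=True)
class FFLMotif:
    tf: str
    mirna: str
    gene: str
    sign_tf_mirna: int
    sign_mirna_gene: int
    sign_tf_gene: int
    coherence: str
    type_label: str


@dataclass(frozen=True)
class FeedbackLoop:
    gene: str
    mirna: str
    sign_gene_mirna: int
    sign_mirna_gene: int

    @property
    def loop_sign(self) -> int:
        return self.sign_gene_mirna * self.sign_mirna_gene


class SignedRegulatoryNetwork:
    """Directed signed tripartite network keyed by (source, target, layer).

    Duplicate (source, target, layer) triples collapse to one edge; supplying
    the same triple with conflicting signs is an error, as is any role
    combination other than TF, gene, miRNA or the dual TF+gene.
    """

    def __init__(self) -> None:
        self._edges: dict[tuple, int] = {}
        self.roles: dict[str, set] = {}

    def add_edge(self, edge: SignedEdge) -> None:
        key = (edge.source, edge.target, edge.layer)
        if key in self._edges:
            if self._edges[key] != edge.sign:
                raise ValueError(f"conflicting signs for edge {key}")
            return
        src_role, tgt_role = LAYERS[edge.layer]
        for node, role in ((edge.source, src_role), (edge.target, tgt_role)):
            combined = self.roles.get(node, set()) | {role}
            if combined not in _ALLOWED_ROLE_SETS:
                raise ValueError(
                    f"node {node!r} would carry roles {sorted(combined)}; "
                    "only TF, gene, miRNA or the dual TF+gene are allowed"
                )
            self.roles[node] = combined
        self._edges[key] = edge.sign

    @property
    def edges(self) -> list[SignedEdge]:
        return [SignedEdge(s, t, sign, layer) for (s, t, layer), sign in self._edges.items()]

    def edges_in_layer(self, layer: str) -> list[SignedEdge]:
        return [e for e in self.edges if e.layer == layer]

    def sign(self, source, target, layer) -> int | None:
        return self._edges.get((source, target, layer))

    @property
    def n_nodes(self) -> int:
        return len(self.roles)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def nodes_with_role(self, role: str) -> set:
        return {n for n, roles in self.roles.items() if role in roles}

    def summary(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "nodes_per_role": {r: len(self.nodes_with_role(r)) for r in ("TF", "miRNA", "gene")},
            "edges_per_layer": {
                layer: sum(1 for k in self._edges if k[2] == layer) for layer in LAYERS
            },
        }


def consensus_targets(
    sources: Mapping[str, Iterable[tuple]], min_support: int | None = None
) -> set:
    """(miRNA, gene) pairs supported by at least ``min_support`` sources.

    ``min_support`` defaults to the number of sources (strict intersection,
    i.e. a pair must be predicted by every database).
    """
    if not sources:
        raise ValueError("need at least one target source")
    if min_support is None:
        min_support = len(sources)
    if not 1 <= min_support <= len(sources):
        raise ValueError(
            f"min_support must be in [1, {len(sources)}], got {min_support}"
        )
    counts: dict[tuple, int] = {}
    for pairs in sources.values():
        for pair in set(map(tuple, pairs)):
            counts[pair] = counts.get(pair, 0) + 1
    return {pair for pair, c in counts.items() if c >= min_support}


def assemble(*edge_lists: Sequence[SignedEdge]) -> SignedRegulatoryNetwork:
    """Build a deduplicated signed regulatory network from per-layer edge lists."""
    net = SignedRegulatoryNetwork()
    for edges in edge_lists:
        for edge in edges:
            net.add_edge(edge)
    return net


def classify_ffl(
    sign_tf_mirna: int, sign_mirna_gene: int, sign_tf_gene: int
) -> tuple[str, str]:
    """Classify a sign triple: ('coherent'|'incoherent', type label C1-C4/I1-I4)."""
    key = (sign_tf_mirna, sign_mirna_gene, sign_tf_gene)
    if key not in FFL_TYPE_TABLE:
        raise ValueError(f"signs must each be +1 or -1, got {key}")
    coherence = "coherent" if sign_tf_gene == sign_tf_mirna * sign_mirna_gene else "incoherent"
    return coherence, FFL_TYPE_TABLE[key]


def enumerate_ffls(net: SignedRegulatoryNetwork) -> list[FFLMotif]:
    """All (TF, miRNA, gene) triples carrying TF->miRNA, miRNA->gene and TF->gene edges.

    Deterministic order: sorted by (tf, mirna, gene).
    """
    mirna_targets: dict[str, list] = {}
    for e in net.edges_in_layer("mirna_gene"):
        mirna_targets.setdefault(e.source, []).append((e.target, e.sign))
    motifs = []
    for tm in net.edges_in_layer("tf_mirna"):
        for gene, s2 in mirna_targets.get(tm.target, ()):
            s3 = net.sign(tm.source, gene, "tf_gene")
            if s3 is None or gene == tm.source:
                continue
            coherence, label = classify_ffl(tm.sign, s2, s3)
            motifs.append(
                FFLMotif(tm.source, tm.target, gene, tm.sign, s2, s3, coherence, label)
            )
    return sorted(motifs, key=lambda m: (m.tf, m.mirna, m.gene))


def enumerate_feedback_loops(net: SignedRegulatoryNetwork) -> list[FeedbackLoop]:
    """All reciprocal gene->miRNA / miRNA->gene pairs, sorted by (gene, mirna)."""
    loops = []
    for gm in net.edges_in_layer("gene_mirna"):
        s_mg = net.sign(gm.target, gm.source, "mirna_gene")
        if s_mg is not None:
            loops.append(FeedbackLoop(gm.source, gm.target, gm.sign, s_mg))
    return sorted(loops, key=lambda l: (l.gene, l.mirna))
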