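"""Readers and writers for interaction-network and regulatory-edge formats.

Undirected protein-protein interaction networks come in as SIF or two-column
TSV edge lists and are returned as simple :class:`networkx.Graph` objects
(self-loops and duplicate edges dropped, identifiers whitespace-trimmed).
Signed regulatory layers (TF->gene, TF->miRNA, miRNA->gene, gene->miRNA) come
in as three-column TSVs, gene-set annotations as GMT.  Writers emit TSV with a
header plus a small JSON provenance sidecar (input path, row counts, dropped
rows).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkFormatError",
    "SignedEdge",
    "AnnotationSet",
    "LAYERS",
    "normalize_identifier",
    "read_network",
    "write_network",
    "read_signed_edges",
    "write_signed_edges",
    "read_gene_sets",
]

#: regulatory layers mapped to the roles their endpoints must carry
LAYERS = {
    "tf_gene": ("TF", "gene"),
    "tf_mirna": ("TF", "miRNA"),
    "mirna_gene": ("miRNA", "gene"),
    "gene_mirna": ("gene", "miRNA"),
}

_SIGN_TOKENS = {
    "activate": 1,
    "+": 1,
    "+1": 1,
    "repress": -1,
    "-": -1,
    "-1": -1,
}

_EDGE_HEADER = ("source", "target")

_MIRNA_RE = re.compile(r"^(hsa-)?(mir|let)-(.+)$", re.IGNORECASE)


class NetworkFormatError(ValueError):
    """Malformed or empty input file."""


@dataclass(frozen=True)
class SignedEdge:
    """A directed regulatory edge with sign +1 (activation) or -1 (repression)."""

    source: str
    target: str
    sign: int
    layer: str

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign!r}")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {sorted(LAYERS)}")


@dataclass(frozen=True)
class AnnotationSet:
    """A named gene set (one GMT line)."""

    term_id: str
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"annotation set {self.term_id!r} has no members")


def normalize_identifier(name: str) -> str:
    """Trim and case-normalize a molecule identifier.

    Gene symbols are upper-cased; miRNA names keep the canonical ``hsa-``
    (lower) / ``miR`` / ``let`` capitalization with a lower-cased suffix, so
    ``MIR-429`` and ``hsa-miR-429`` normalize consistently.
    """
    name = name.strip()
    m = _MIRNA_RE.match(name)
    if m:
        prefix = "hsa-" if m.group(1) else ""
        stem = "miR" if m.group(2).lower() == "mir" else "let"
        return f"{prefix}{stem}-{m.group(3).lower()}"
    return name.upper()


def _clean(token: str, normalize: bool) -> str:
    return normalize_identifier(token) if normalize else token.strip()


def _iter_rows(path: Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.strip():
                yield lineno, line


def read_network(path, format: str | None = None, normalize: bool = False) -> nx.Graph:
    """Read an undirected interaction network from SIF or 2-column TSV.

    Parameters
    ----------
    path
        Input file.  ``format`` defaults to ``"sif"`` for a ``.sif`` suffix
        and ``"tsv"`` otherwise.
    normalize
        Apply :func:`normalize_identifier` to every node id.

    Returns
    -------
    networkx.Graph
        A simple graph.  Self-loops and duplicate edges are dropped (counts
        recorded in ``G.graph["provenance"]`` and logged).  Multi-target SIF
        rows (``A pp B C``) expand to a star from the first node.
    """
    path = Path(path)
    if format is None:
        format = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if format not in ("sif", "tsv"):
        raise ValueError(f"format must be 'sif' or 'tsv', got {format!r}")

    graph = nx.Graph()
    n_rows = n_self_loops = n_duplicates = 0
    for lineno, line in _iter_rows(path):
        if format == "tsv":
            fields = line.split("\t")
            if n_rows == 0 and tuple(f.strip().lower() for f in fields) == _EDGE_HEADER:
                continue  # header emitted by write_network
            if len(fields) != 2:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            pairs = [(fields[0], fields[1])]
        else:
            tokens = line.split()
            if len(tokens) == 1:
                graph.add_node(_clean(tokens[0], normalize))
                n_rows += 1
                continue
            if len(tokens) == 2:
                raise NetworkFormatError(
                    f"{path}:{lineno}: SIF row needs 'source interaction target...', got 2 tokens"
                )
            pairs = [(tokens[0], t) for t in tokens[2:]]
        n_rows += 1
        for a, b in pairs:
            a, b = _clean(a, normalize), _clean(b, normalize)
            if not a or not b:
                raise NetworkFormatError(f"{path}:{lineno}: empty identifier")
            if a == b:
                n_self_loops += 1
                graph.add_node(a)
            elif graph.has_edge(a, b):
                n_duplicates += 1
            else:
                graph.add_edge(a, b)

    if graph.number_of_nodes() == 0:
        raise NetworkFormatError(f"{path}: empty network (no rows)")
    if n_self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_self_loops)
    graph.graph["provenance"] = {
        "path": str(path),
        "format": format,
        "rows": n_rows,
        "self_loops_dropped": n_self_loops,
        "duplicates_dropped": n_duplicates,
    }
    return graph


def _write_sidecar(path: Path, provenance: dict) -> None:
    with open(str(path) + ".prov.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_network(net: nx.Graph, path, provenance: dict | None = None) -> None:
    """Write an edge-list TSV (header ``source<TAB>target``) plus provenance sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{a}\t{b}\n")
    prov = dict(provenance or {})
    prov.update(net.graph.get("provenance", {}))
    prov.update({"nodes": net.number_of_nodes(), "edges": net.number_of_edges()})
    _write_sidecar(path, prov)


def read_signed_edges(
    path,
    layer: str,
    normalize: bool = False,
    default_sign: int | None = None,
) -> list[SignedEdge]:
    """Read a signed 3-column TSV (source, target, sign) for one regulatory layer.

    Sign tokens accepted (case-insensitive): ``activate``, ``repress``, ``+``,
    ``-``, ``+1``, ``-1``.  When ``default_sign`` is given, two-column rows are
    allowed and take that sign (used for miRNA->target lists, which are
    repressive by convention).
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {sorted(LAYERS)}")
    path = Path(path)
    edges: list[SignedEdge] = []
    for lineno, line in _iter_rows(path):
        fields = [f.strip() for f in line.split("\t")]
        if (
            not edges
            and lineno == 1
            and tuple(f.lower() for f in fields[:2]) == _EDGE_HEADER
        ):
            continue  # header emitted by write_signed_edges
        if len(fields) == 2 and default_sign is not None:
            sign = default_sign
        elif len(fields) == 3:
            token = fields[2].lower()
            if token not in _SIGN_TOKENS:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown sign token {fields[2]!r} "
                    f"(expected one of {sorted(_SIGN_TOKENS)})"
                )
            sign = _SIGN_TOKENS[token]
        else:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        edges.append(
            SignedEdge(_clean(fields[0], normalize), _clean(fields[1], normalize), sign, layer)
        )
    return edges


def write_signed_edges(edges: Sequence[SignedEdge], path, provenance: dict | None = None) -> None:
    """Write signed edges as TSV (source, target, sign, layer) plus provenance sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsign\tlayer\n")
        for e in edges:
            fh.write(f"{e.source}\t{e.target}\t{e.sign:+d}\t{e.layer}\n")
    prov = dict(provenance or {})
    prov["edges"] = len(edges)
    _write_sidecar(path, prov)


def read_gene_sets(path, normalize: bool = False) -> list[AnnotationSet]:
    """Read a GMT file: ``term<TAB>description<TAB>member...``, one set per line.

    Duplicate members within a line are collapsed; duplicate term ids across
    lines are an error.
    """
    path = Path(path)
    sets: list[AnnotationSet] = []
    seen: set[str] = set()
    for lineno, line in _iter_rows(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise NetworkFormatError(
                f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}"
            )
        term_id = fields[0].strip()
        if term_id in seen:
            raise NetworkFormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
        seen.add(term_id)
        members = frozenset(_clean(m, normalize) for m in fields[2:] if m.strip())
        if not members:
            raise NetworkFormatError(f"{path}:{lineno}: term {term_id!r} has no members")
        sets.append(AnnotationSet(term_id, fields[1].strip(), members))
    return sets
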