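"""Hubs, bottlenecks and bottleneck-hubs.

Hubs are the top-n nodes by degree, bottlenecks the top-n by betweenness
centrality; the intersection of the two lists (ordered by hub rank) is the
bottleneck-hub set, the nodes that both concentrate connections and control
shortest-path traffic.  Ties are broken by metric descending then node id
ascending, and the top-n cut is strict (tied tails are not expanded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

__all__ = ["KeyNodeReport", "rank_nodes", "intersect_key_nodes", "key_node_report"]

_RANK_FIELDS = {"degree": "degree", "betweenness": "betweenness"}


@dataclass(frozen=True)
class KeyNodeReport:
    hubs: tuple                  # ordered (node, degree)
    bottlenecks: tuple           # ordered (node, betweenness)
    bottleneck_hubs: tuple       # ordered by hub rank

    def to_dict(self) -> dict:
        return {
            "hubs": [[n, v] for n, v in self.hubs],
            "bottlenecks": [[n, v] for n, v in self.bottlenecks],
            "bottleneck_hubs": list(self.bottleneck_hubs),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def rank_nodes(metrics: pd.DataFrame, by: str, n: int = 10) -> list:
    """Top-``n`` (node, value) pairs by ``by`` in {'degree', 'betweenness'}.

    Sorted by value descending, ties by node id ascending; returns
    min(n, node count) entries.
    """
    if by not in _RANK_FIELDS:
        raise ValueError(f"can rank by 'degree' or 'betweenness', not {by!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    col = _RANK_FIELDS[by]
    ordered = sorted(metrics[col].items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [(node, value) for node, value in ordered[:n]]


def intersect_key_nodes(hubs, bottlenecks) -> list:
    """Nodes appearing in both ranked lists, ordered by hub (degree) rank."""
    if not hubs or not bottlenecks:
        raise ValueError("both ranked lists must be non-empty")
    bottleneck_ids = {node for node, _ in bottlenecks}
    return [node for node, _ in hubs if node in bottleneck_ids]


def key_node_report(metrics: pd.DataFrame, n: int = 10) -> KeyNodeReport:
    """Rank hubs and bottlenecks from a node-metrics table and intersect them."""
    hubs = rank_nodes(metrics, "degree", n)
    bottlenecks = rank_nodes(metrics, "betweenness", n)
    return KeyNodeReport(
        hubs=tuple(hubs),
        bottlenecks=tuple(bottlenecks),
        bottleneck_hubs=tuple(intersect_key_nodes(hubs, bottlenecks)),
    )
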