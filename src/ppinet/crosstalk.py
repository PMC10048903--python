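"""Crosstalk between bottleneck-hubs and detected subnetworks.

The interaction strength of a bottleneck-hub b with a subnetwork S is the
number of distinct members of S adjacent to b in the *full* network, b itself
excluded — so a hub sitting inside a 31-member complex can score at most 30
there, and hubs outside a complex still score through their edges into it.
The hub with the largest row total over all subnetworks is the key mediator.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import pandas as pd

from .mcode import Complex

__all__ = ["interaction_strength", "crosstalk_matrix", "key_mediator", "matrix_from_cells"]


def interaction_strength(net: nx.Graph, bnh, complex: Complex) -> int:
    """Distinct complex members adjacent to ``bnh`` in the full network (self excluded)."""
    if bnh not in net:
        raise KeyError(f"node {bnh!r} not in network")
    return sum(1 for m in complex.members if m != bnh and net.has_edge(bnh, m))


def crosstalk_matrix(
    net: nx.Graph, bnhs: Sequence, complexes: Sequence[Complex]
) -> pd.DataFrame:
    """Strength matrix (rows: bottleneck-hubs, columns SN-1..SN-k, plus Total).

    Rows are sorted by total descending, ties by node id ascending.
    """
    if not bnhs or not complexes:
        raise ValueError("need at least one bottleneck-hub and one complex")
    columns = [f"SN-{c.rank}" for c in complexes]
    data = {
        b: [interaction_strength(net, b, c) for c in complexes] for b in bnhs
    }
    matrix = pd.DataFrame.from_dict(data, orient="index", columns=columns)
    matrix.index.name = "bnh"
    return _finalize(matrix)


def matrix_from_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Build a crosstalk matrix from precomputed strength cells (replay input).

    ``cells`` is indexed by bottleneck-hub with one column per subnetwork; any
    existing ``Total`` column is dropped and recomputed.
    """
    matrix = cells.drop(columns=["Total"], errors="ignore").astype(int)
    matrix.index.name = "bnh"
    return _finalize(matrix)


def _finalize(matrix: pd.DataFrame) -> pd.DataFrame:
    matrix = matrix.copy()
    matrix["Total"] = matrix.sum(axis=1)
    order = sorted(matrix.index, key=lambda b: (-matrix.at[b, "Total"], str(b)))
    return matrix.loc[order]


def key_mediator(matrix: pd.DataFrame):
    """Bottleneck-hub with the maximum row total; ties broken by node id."""
    if matrix.empty:
        raise ValueError("empty crosstalk matrix")
    totals = matrix["Total"]
    best = totals.max()
    return sorted(b for b in matrix.index if totals[b] == best)[0]
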