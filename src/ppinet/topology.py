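"""Per-node topological metrics, degree aggregation and log-log power-law fits.

Six metrics are computed per node: degree k, clustering coefficient
C = 2m_i / (k_i (k_i - 1)), neighborhood connectivity (mean neighbor degree),
betweenness centrality (normalized by (n-1)(n-2)/2, endpoints excluded),
closeness centrality, and eigenvector centrality.  A hierarchical scale-free
network shows P(k) ~ k^-gamma together with C(k) decaying roughly like k^-1,
and a disassortative network shows mean neighbor degree falling with k; both
signatures are read off ordinary least-squares fits of log10(mean metric)
against log10(k), one point per observed degree.

Closeness follows the per-component convention (reachable - 1) / sum of
distances rather than the textbook N / sum-of-distances form, so values stay
in [0, 1] on disconnected networks.  Eigenvector centrality is a deterministic
power iteration on A + I (the shift guarantees convergence on connected
bipartite graphs), started from the uniform vector and L2-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "METRIC_FIELDS",
    "PowerLawFit",
    "InsufficientDataError",
    "compute_node_metrics",
    "degree_distribution",
    "aggregate_by_degree",
    "fit_power_law",
    "eigenvector_centrality",
]

#: metric columns of the node-metrics table, in output order
METRIC_FIELDS = (
    "degree",
    "clustering",
    "neighborhood_connectivity",
    "betweenness",
    "closeness",
    "eigenvector",
)


class InsufficientDataError(ValueError):
    """Too few strictly positive points for a log-log fit."""


class PowerIterationError(RuntimeError):
    """Eigenvector power iteration failed to converge."""


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(y) on log10(k).

    ``slope`` is the fitted exponent (a decaying law y ~ k^-g has slope -g),
    ``pearson_r`` the correlation of the log-log points.  ``degenerate`` marks
    a constant-y fit, reported as slope 0 with r set to 0.
    """

    slope: float
    intercept: float
    pearson_r: float
    n_points: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def eigenvector_centrality(
    net: nx.Graph, tol: float = 1e-12, max_iter: int = 5000
) -> dict:
    """Principal-eigenvector centrality by power iteration on A + I.

    Deterministic: uniform start vector, L2 normalization each step, stop when
    the L2 change between iterates falls below ``tol``.  On a connected graph
    all scores are non-negative and the score vector has unit L2 norm.
    """
    nodes = list(net)
    if not nodes:
        raise ValueError("empty network")
    A = nx.to_numpy_array(net, nodelist=nodes)
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        y = A @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:  # edgeless graph: uniform vector is already the answer
            return dict(zip(nodes, x))
        y /= norm
        if np.linalg.norm(y - x) < tol:
            return dict(zip(nodes, y))
        x = y
    raise PowerIterationError(f"no convergence within {max_iter} iterations (tol={tol})")


def compute_node_metrics(net: nx.Graph) -> pd.DataFrame:
    """Compute the six per-node metrics.

    Returns a DataFrame indexed by node with columns :data:`METRIC_FIELDS`.
    Clustering of a degree-<2 node is 0; neighborhood connectivity of an
    isolated node is 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = list(net)
    degree = dict(net.degree())
    table = pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "clustering": pd.Series(nx.clustering(net)).reindex(nodes).to_numpy(),
            "neighborhood_connectivity": pd.Series(nx.average_neighbor_degree(net))
            .reindex(nodes)
            .fillna(0.0)
            .to_numpy(),
            "betweenness": pd.Series(nx.betweenness_centrality(net, normalized=True))
            .reindex(nodes)
            .to_numpy(),
            "closeness": pd.Series(nx.closeness_centrality(net, wf_improved=False))
            .reindex(nodes)
            .to_numpy(),
            "eigenvector": pd.Series(eigenvector_centrality(net)).reindex(nodes).to_numpy(),
        },
        index=pd.Index(nodes, name="node"),
    )
    return table


def degree_distribution(net: nx.Graph) -> dict:
    """Empirical degree distribution P(k) = N_k / N over observed degrees."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = pd.Series(dict(net.degree()))
    counts = degrees.value_counts().sort_index()
    return (counts / len(degrees)).to_dict()


def aggregate_by_degree(metrics: pd.DataFrame, metric: str) -> dict:
    """Mean of ``metric`` over nodes of each observed degree, keyed by degree."""
    if metric not in METRIC_FIELDS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRIC_FIELDS}")
    grouped = metrics.groupby("degree")[metric].mean()
    return {int(k): float(v) for k, v in grouped.items()}


def fit_power_law(agg: Mapping[int, float], min_points: int = 3) -> PowerLawFit:
    """Fit log10(y) = intercept + slope * log10(k) over strictly positive points.

    Degrees k <= 0 and values y <= 0 are excluded (a zero mean carries no
    log-log information).  Fewer than ``min_points`` usable points raises
    :class:`InsufficientDataError`; constant y returns a degenerate fit with
    slope 0 and r reported as 0.
    """
    pts = [(k, y) for k, y in agg.items() if k > 0 and y > 0]
    if len(pts) < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} strictly positive (k, y) points, got {len(pts)}"
        )
    logk = np.log10([k for k, _ in pts])
    logy = np.log10([y for _, y in pts])
    if np.allclose(logy, logy[0]):
        return PowerLawFit(0.0, float(logy[0]), 0.0, len(pts), degenerate=True)
    res = stats.linregress(logk, logy)
    return PowerLawFit(
        float(res.slope), float(res.intercept), float(res.rvalue), len(pts)
    )


def fit_metric_vs_degree(metrics: pd.DataFrame, metric: str) -> PowerLawFit:
    """Convenience: aggregate ``metric`` by degree and fit the power law."""
    return fit_power_law(aggregate_by_degree(metrics, metric))
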