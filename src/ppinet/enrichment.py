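"""Over-representation analysis (ORA) of a query set against gene-set annotations.

For a background of N identifiers, a term with K annotated members and a
query of n identifiers overlapping the term in k, the enrichment p-value is
the hypergeometric upper tail P(X >= k).  P-values are Benjamini-Hochberg
adjusted across terms, and an odds ratio is reported from the 2x2 table
(with a Haldane 0.5 correction when any cell is zero).  This is the generic
local mechanism behind GO/pathway enrichment servers; it uses only
user-supplied gene sets and makes no web calls.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .netio import AnnotationSet

__all__ = ["ora"]

RESULT_COLUMNS = [
    "term_id",
    "term_name",
    "overlap",
    "query_size",
    "term_size",
    "background_size",
    "p_value",
    "adjusted_p",
    "odds_ratio",
    "significant",
]


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if b * c == 0:  # Haldane correction only where the ratio is undefined
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def ora(
    query: Iterable,
    gene_sets: Sequence[AnnotationSet],
    background: Iterable | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each annotation set.

    ``background`` defaults to the union of all annotation members (the
    "only annotated" domain convention); the query must be a subset of it.
    Each term is intersected with the background before testing.  Results are
    sorted by p-value ascending, with BH-adjusted p-values and a
    ``significant`` flag at ``alpha`` on the adjusted values.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    if not gene_sets:
        raise ValueError("no annotation sets supplied")
    if background is None:
        background = set().union(*(s.members for s in gene_sets))
    else:
        background = set(background)
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        missing = sorted(query - background)[:5]
        raise ValueError(f"query not a subset of background (e.g. {missing})")

    N, n = len(background), len(query)
    rows = []
    for s in gene_sets:
        members = s.members & background
        if not members:
            continue
        K = len(members)
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((s.term_id, s.name, k, n, K, N, min(p, 1.0), _odds_ratio(k, n, K, N)))
    result = pd.DataFrame(
        rows,
        columns=[c for c in RESULT_COLUMNS if c not in ("adjusted_p", "significant")],
    )
    result["adjusted_p"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result["significant"] = result["adjusted_p"] <= alpha
    result = result[RESULT_COLUMNS]
    return result.sort_values(
        ["p_value", "term_id"], kind="mergesort", ignore_index=True
    )
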