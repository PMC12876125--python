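"""Over-representation analysis of gene sets (GO-style BP/MF/CC).

The query — here, a tissue's differentially expressed ligands — is tested
against each annotation term with the one-sided hypergeometric tail
P(X >= k), where k is the number of query genes in the term, K the term size
within the background, n the query size and N the background size. The
background is the measured gene universe (all genes present in the tissue's
expression matrix after probe collapsing), not the whole genome. Adjustment
is Benjamini-Hochberg, by default within each GO category separately, the way
category-grouped dot plots are conventionally built; terms with zero query
hits are excluded from testing (and hence from the number of tests m).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .containers import GeneSetAnnotation
from .errors import ParameterError

__all__ = ["hypergeom_tail", "bh_adjust", "enrich"]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the population (background) size, K the number of successes in the
    population (term size), n the draw (query) size and k the observed hits.
    The tail is accumulated in log space for numerical stability.
    """
    if min(k, K, n, N) < 0 or K > N or n > N or k > min(K, n):
        raise ParameterError(f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    logpmf = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def enrich(
    query: Iterable[str],
    annotation: GeneSetAnnotation,
    background: Iterable[str],
    per_category: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each annotation term.

    Term member sets are intersected with the background before counting, so
    genes outside the measured universe never influence any count. Only terms
    with at least one query hit are tested. Returns a DataFrame sorted by
    p-value ascending (ties by term_id) with columns term_id, term_name,
    category, k, K, n, N, p_value, adj_p, gene_ratio, hit_genes.
    """
    background_set = frozenset(background)
    query_set = frozenset(query)
    if not background_set or not query_set:
        raise ParameterError("query and background must be nonempty")
    if not query_set <= background_set:
        extra = sorted(query_set - background_set)
        raise ParameterError(f"query genes missing from background: {extra[:5]}")
    N = len(background_set)
    n = len(query_set)
    rows = []
    for term in annotation.terms:
        members = term.genes & background_set
        hits = members & query_set
        if not hits:
            continue
        k, K = len(hits), len(members)
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "category": term.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeom_tail(k, K, n, N),
                "gene_ratio": k / n,
                "hit_genes": ",".join(sorted(hits)),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "category",
            "k",
            "K",
            "n",
            "N",
            "p_value",
            "gene_ratio",
            "hit_genes",
        ],
    )
    if result.empty:
        result["adj_p"] = pd.Series(dtype=float)
    elif per_category:
        result["adj_p"] = np.nan
        for cat, idx in result.groupby("category").groups.items():
            result.loc[idx, "adj_p"] = bh_adjust(result.loc[idx, "p_value"])
    else:
        result["adj_p"] = bh_adjust(result["p_value"])
    result = result.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    cols = [
        "term_id",
        "term_name",
        "category",
        "k",
        "K",
        "n",
        "N",
        "p_value",
        "adj_p",
        "gene_ratio",
        "hit_genes",
    ]
    return result[cols]
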