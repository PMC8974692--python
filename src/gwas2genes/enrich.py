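"""Gene-set term enrichment: overlap counts, fold enrichment and tail p.

For a query of n genes against a term of K genes in a background of N, the
overlap k is scored by the hypergeometric upper tail P[X >= k] and by the
fold enrichment FE = (k/n)/(K/N).  The default mode is the conservative
EASE variant (overlap reduced by one before taking the tail), matching the
DAVID-style analyses this stage emulates; the plain hypergeometric tail is
available as ``mode="hypergeometric"``.  Term-level multiplicity is handled
with the Benjamini-Hochberg linear step-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, ValidationError

logger = logging.getLogger("gwas2genes")

__all__ = ["EnrichmentResult", "term_enrichment", "percent_of_query"]

_MODES = ("hypergeometric", "ease")


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one term against the query set."""

    term: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_value: float
    fdr_q: float
    percent: float


def _tail_p(k: int, N: int, K: int, n: int, mode: str) -> float:
    """Upper-tail overlap probability; EASE mode uses max(k-1, 0)."""
    k_eff = max(k - 1, 0) if mode == "ease" else k
    if k_eff <= 0:
        return 1.0
    # sf(k_eff - 1) = P[X >= k_eff]
    return float(stats.hypergeom.sf(k_eff - 1, N, K, n))


def percent_of_query(k: int, n: int) -> float:
    """Overlap as a percentage of the query set, to two decimals."""
    if n <= 0 or not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    return round(100.0 * k / n, 2)


def term_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    mode: str = "ease",
    fdr_q: float = 0.05,
) -> list[EnrichmentResult]:
    """Score every term of ``collection`` against ``query``.

    Query genes outside the background are dropped with a warning.  Results
    are sorted by ascending p (stable for ties); ``fdr_q`` is only used to
    pick the step-up level for the reported q-values, which callers compare
    to their significance cutoff.
    """
    if mode not in _MODES:
        raise ValidationError(f"mode must be one of {_MODES}, got {mode!r}")
    query = set(query)
    if not query:
        raise ValidationError("query gene set is empty")
    if not collection.background:
        raise ValidationError("background gene set is empty")
    dropped = query - collection.background
    if dropped:
        logger.warning(
            "dropping %d query gene(s) outside the background: %s",
            len(dropped),
            sorted(dropped)[:10],
        )
    query &= collection.background
    if not query:
        raise ValidationError("no query genes remain inside the background")

    n = len(query)
    N = len(collection.background)
    partial: list[tuple[str, int, int, float, float]] = []
    for term, genes in collection.terms.items():
        K = len(genes)
        k = len(query & genes)
        fe = 0.0 if k == 0 else (k / n) / (K / N)
        p = _tail_p(k, N, K, n, mode)
        partial.append((term, k, K, fe, p))

    pvals = [p for *_, p in partial]
    _, qvals, _, _ = multipletests(pvals, alpha=fdr_q, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=term,
            k=k,
            n=n,
            K=K,
            N=N,
            fold_enrichment=fe,
            p_value=p,
            fdr_q=float(qv),
            percent=percent_of_query(k, n),
        )
        for (term, k, K, fe, p), qv in zip(partial, qvals)
    ]
    results.sort(key=lambda r: r.p_value)
    return results
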