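"""Hypergeometric GO-term over-representation with Bonferroni correction.

The universe is the set of genes present in the annotation; the test for
a term with K universe genes asks whether the k candidates carrying it
exceed the expectation under uniform sampling of n candidates from N
universe genes (upper-tail hypergeometric).  Terms annotating no
candidate (k = 0) are excluded from testing and from the Bonferroni
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["EnrichmentResult", "hypergeom_upper_p", "enrich"]


@dataclass
class EnrichmentResult:
    term: str
    k: int  # candidates with the term
    K: int  # universe genes with the term
    n: int  # candidate count
    N: int  # universe size
    p_raw: float
    p_adj: float


def hypergeom_upper_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) (log-gamma stable)."""
    if not (0 <= k <= n <= N) or not (0 <= K <= N) or k > K:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def enrich(
    candidates: set[str] | list[str],
    annotation: pd.DataFrame,
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Test every term annotating >= 1 candidate gene.

    ``annotation`` has columns gene_id, term_id (one pair per line).
    The universe defaults to all genes in the annotation; candidates must
    be a subset of the universe.  Results carry Bonferroni-adjusted P
    over the number of terms actually tested and are sorted by p_adj,
    then p_raw, then term id.
    """
    cand = set(candidates)
    if universe is None:
        universe = set(annotation["gene_id"])
    if not cand <= universe:
        missing = sorted(cand - universe)[:5]
        raise ValueError(f"candidates outside the universe, e.g. {missing}")
    ann = annotation[annotation["gene_id"].isin(universe)]
    N = len(universe)
    n = len(cand)
    term_genes = ann.groupby("term_id")["gene_id"].agg(set)
    tested: list[EnrichmentResult] = []
    for term, genes in term_genes.items():
        k = len(genes & cand)
        if k == 0:
            continue
        tested.append(
            EnrichmentResult(
                term=str(term),
                k=k,
                K=len(genes),
                n=n,
                N=N,
                p_raw=hypergeom_upper_p(k, len(genes), n, N),
                p_adj=1.0,
            )
        )
    m = len(tested)
    for r in tested:
        r.p_adj = min(1.0, r.p_raw * m)
    tested.sort(key=lambda r: (r.p_adj, r.p_raw, r.term))
    return tested
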