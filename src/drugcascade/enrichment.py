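"""Over-representation analysis of gene sets against GMT collections.

One-sided hypergeometric upper-tail test: for a query of ``n`` genes drawn
from a universe of ``N``, a term annotating ``K`` universe genes, and an
observed overlap ``k``, the enrichment p-value is P(X >= k) with
X ~ Hypergeometric(N, K, n).  Terms are filtered at raw p < alpha
(default 0.01); Benjamini–Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationCollection",
    "EnrichmentResult",
    "hypergeometric_upper_tail",
    "enrich",
    "read_gmt",
    "write_enrichment_table",
]


class AnnotationCollection:
    """term-id -> (term name, gene set); symbols canonicalized upper-case."""

    def __init__(self, terms: Mapping[str, tuple[str, Iterable[str]]]):
        self.terms: dict[str, tuple[str, frozenset[str]]] = {}
        for term_id, (name, genes) in terms.items():
            gene_set = frozenset(g.upper() for g in genes)
            if not gene_set:
                raise ValueError(f"term {term_id!r} has an empty gene set")
            if term_id in self.terms:
                raise ValueError(f"duplicate term id {term_id!r}")
            self.terms[term_id] = (name, gene_set)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    k: int  # overlap
    K: int  # term size within universe
    n: int  # query size within universe
    N: int  # universe size
    p_value: float
    significant: bool
    p_adjusted: float | None = None


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Delegates to scipy's survival function, which works in log space and
    is numerically stable for extreme tails.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    collection: AnnotationCollection,
    universe: Iterable[str],
    alpha: float = 0.01,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Test every collection term for over-representation in the query.

    Query genes outside the universe are dropped with a warning.  One
    result per term with overlap >= 1 after intersecting term sets with the
    universe, sorted by p ascending then term-id.  ``significant`` uses raw
    p < alpha by default; with ``adjust=True`` BH-adjusted p is thresholded
    instead.
    """
    uni = {g.upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    q_raw = {g.upper() for g in query}
    q = q_raw & uni
    if q != q_raw:
        warnings.warn(
            f"{len(q_raw - uni)} query gene(s) outside the universe were dropped"
        )
    if not q:
        warnings.warn("query empty after universe intersection")
        return []
    N, n = len(uni), len(q)
    results = []
    for term_id, (name, genes) in collection.terms.items():
        term_in_uni = genes & uni
        k = len(term_in_uni & q)
        if k < 1:
            continue
        K = len(term_in_uni)
        p = hypergeometric_upper_tail(k, K, n, N)
        results.append(EnrichmentResult(term_id, name, k, K, n, N, p, p < alpha))
    results.sort(key=lambda r: (r.p_value, r.term_id))
    if adjust and results:
        _, p_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        results = [
            EnrichmentResult(
                r.term_id, r.name, r.k, r.K, r.n, r.N, r.p_value,
                float(pa) < alpha, float(pa),
            )
            for r, pa in zip(results, p_adj)
        ]
    return results


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file: term<TAB>description<TAB>gene1<TAB>gene2..."""
    terms: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: GMT line needs term, description, genes")
            terms[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return AnnotationCollection(terms)


def write_enrichment_table(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tname\tk\tK\tn\tN\tp\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_value:.6g}\t{str(r.significant).lower()}\n"
            )
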