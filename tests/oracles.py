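"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — position-by-position scans,
exhaustive subset/path enumeration, direct numerical integration — and
shares no code path with the package.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import integrate, stats


def exhaustive_mention_scan(
    text: str, surface_to_symbol: dict[str, str], blocklist: set[str]
) -> list[tuple[int, int, str]]:
    """Left-to-right longest-match scan with word-boundary checks.

    Returns (start, end, symbol) triples.  A position matches a surface
    form iff the uppercased slice equals the form and both neighbours are
    non-alphanumeric or string edges.
    """
    upper = text.upper()
    forms = sorted(
        (f for f in surface_to_symbol if f not in blocklist),
        key=len, reverse=True,
    )
    hits = []
    i = 0
    n = len(text)
    while i < n:
        matched = None
        for form in forms:  # longest first
            j = i + len(form)
            if j > n or upper[i:j] != form:
                continue
            before_ok = i == 0 or not text[i - 1].isalnum()
            after_ok = j == n or not text[j].isalnum()
            if before_ok and after_ok:
                matched = (i, j, surface_to_symbol[form])
                break
        if matched:
            hits.append(matched)
            i = matched[1]
        else:
            i += 1
    return hits


def all_simple_paths_brute(
    adj: dict[str, set[str]], src: str, dst: str, cutoff: int
) -> list[tuple[str, ...]]:
    """All simple src→dst paths with <= cutoff edges, by recursive DFS."""
    out: list[tuple[str, ...]] = []

    def walk(node: str, path: list[str]):
        if node == dst:
            out.append(tuple(path))
            return
        if len(path) - 1 >= cutoff:
            return
        for nxt in sorted(adj.get(node, ())):
            if nxt not in path:
                walk(nxt, path + [nxt])

    if src == dst:
        return [(src,)]
    walk(src, [src])
    return out


def shortest_paths_brute(
    adj: dict[str, set[str]], sources: list[str], dst: str
) -> list[tuple[str, ...]]:
    """Minimum-length simple paths from any source, via full enumeration."""
    n_nodes = len(adj)
    all_paths: list[tuple[str, ...]] = []
    for s in sources:
        all_paths.extend(all_simple_paths_brute(adj, s, dst, cutoff=n_nodes))
    if not all_paths:
        return []
    best = min(len(p) - 1 for p in all_paths)
    return sorted((p for p in all_paths if len(p) - 1 == best))


def hypergeom_upper_tail_enum(k: int, K: int, n: int, N: int) -> Fraction:
    """P(overlap >= k) by enumerating all C(N, n) equally likely draws."""
    hits = sum(
        1 for draw in combinations(range(N), n) if sum(x < K for x in draw) >= k
    )
    return Fraction(hits, comb(N, n))


def studentized_range_sf_numeric(q: float, k: int, df: int) -> float:
    """Upper tail of the studentized range by direct double integration.

    Q = R / S where R is the range of k iid standard normals and
    S^2 ~ chi2_df / df.  P(Q <= q) = E_S[ P(R <= q S) ] with
    P(R <= r) = k * int phi(z) [Phi(z + r) - Phi(z)]^(k-1) dz.
    """

    def range_cdf(r: float) -> float:
        if r <= 0:
            return 0.0
        val, _ = integrate.quad(
            lambda z: stats.norm.pdf(z)
            * (stats.norm.cdf(z + r) - stats.norm.cdf(z)) ** (k - 1),
            -np.inf, np.inf,
        )
        return k * val

    chi = stats.chi2(df)
    cdf, _ = integrate.quad(
        lambda u: range_cdf(q * sqrt(u / df)) * chi.pdf(u), 0, np.inf,
        limit=200,
    )
    return 1.0 - cdf
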