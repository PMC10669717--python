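"""Abstract-corpus curation, dictionary-based gene/protein mention tagging,
and pointwise-mutual-information (PMI) weighting of disease association.

The mining stage emulates a PubMed.mineR-style workflow: a corpus of
MEDLINE abstracts is filtered by keyword/year/exclusion rules, gene symbols
are matched against a synonym lexicon with word-boundary semantics, and
each symbol's association with the disease term set is weighted by
document-level PMI,

    pmi(x) = log2( n_xd * N / (n_x * n_d) )

where ``N`` is the number of curated abstracts, ``n_x`` the number
mentioning symbol ``x``, ``n_d`` the number matching any disease term, and
``n_xd`` the number doing both.  Counting is per document: repeated
mentions inside one abstract contribute once.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Medline

__all__ = [
    "AbstractRecord",
    "GeneLexicon",
    "MentionHit",
    "CooccurrenceCounts",
    "PmiScore",
    "LexiconError",
    "CurationReport",
    "curate_corpus",
    "match_mentions",
    "count_cooccurrence",
    "compute_pmi",
    "rank_proteins",
    "read_medline",
    "read_structured",
    "write_structured",
    "read_lexicon",
    "write_pmi_table",
]


class LexiconError(ValueError):
    """Raised when a lexicon violates its invariants (e.g. a synonym
    claimed by two canonical symbols)."""


@dataclass(frozen=True)
class AbstractRecord:
    """One abstract: id, title, body text and publication year."""

    record_id: str
    title: str
    body: str
    year: int


@dataclass(frozen=True)
class MentionHit:
    """A lexicon match inside one abstract, with 0-based half-open span."""

    record_id: str
    symbol: str
    start: int
    end: int
    surface: str


@dataclass
class CurationReport:
    """Outcome of corpus curation: retained records plus skip accounting."""

    records: list[AbstractRecord]
    n_input: int
    n_skipped_malformed: int
    n_duplicates: int


# Symbols shorter than this are blocklisted by default: 1-2 letter tokens
# ("AT", "IT", "ER") are pervasive false positives in free text.
MIN_SYMBOL_LEN = 3


class GeneLexicon:
    """Canonical symbol -> synonym-set dictionary with a blocklist.

    Both canonical symbols and synonyms are uppercased at load.  A surface
    form may belong to at most one canonical symbol; collisions either
    raise :class:`LexiconError` (default) or are routed to the blocklist
    (``collisions="block"``).  Symbols/synonyms shorter than
    ``MIN_SYMBOL_LEN`` characters are blocklisted unless explicitly
    whitelisted.
    """

    def __init__(
        self,
        entries: Mapping[str, Iterable[str]],
        blocklist: Iterable[str] = (),
        whitelist: Iterable[str] = (),
        collisions: str = "error",
    ):
        if collisions not in ("error", "block"):
            raise ValueError("collisions must be 'error' or 'block'")
        whitelist_u = {w.upper() for w in whitelist}
        self.blocklist: set[str] = {b.upper() for b in blocklist}
        if self.blocklist & whitelist_u:
            raise LexiconError(
                f"blocklist and whitelist overlap: {sorted(self.blocklist & whitelist_u)}"
            )
        self.entries: dict[str, set[str]] = {}
        surface_owner: dict[str, str] = {}
        for raw_symbol, synonyms in entries.items():
            symbol = raw_symbol.upper()
            forms = {symbol} | {s.upper() for s in synonyms if s.strip()}
            self.entries[symbol] = set()
            for form in forms:
                if len(form) < MIN_SYMBOL_LEN and form not in whitelist_u:
                    self.blocklist.add(form)
                    continue
                owner = surface_owner.get(form)
                if owner is not None and owner != symbol:
                    if collisions == "error":
                        raise LexiconError(
                            f"surface form {form!r} claimed by both {owner} and {symbol}"
                        )
                    self.blocklist.add(form)
                    self.entries[owner].discard(form)
                    continue
                surface_owner[form] = symbol
                self.entries[symbol].add(form)
        # blocklisted forms never match, even if registered above
        for symbol in self.entries:
            self.entries[symbol] -= self.blocklist

    def surface_forms(self) -> dict[str, str]:
        """Map of matchable surface form -> canonical symbol."""
        return {
            form: symbol
            for symbol, forms in self.entries.items()
            for form in forms
            if form not in self.blocklist
        }


@dataclass(frozen=True)
class CooccurrenceCounts:
    """Per-document co-occurrence counts between symbols and disease terms."""

    n_docs: int
    doc_count: Mapping[str, int]
    disease_doc_count: int
    joint_count: Mapping[str, int]

    def __post_init__(self):
        if self.n_docs < 1:
            raise ValueError("empty corpus")
        for sym, n_x in self.doc_count.items():
            n_xd = self.joint_count.get(sym, 0)
            if not (0 <= n_xd <= min(n_x, self.disease_doc_count) <= self.n_docs):
                raise ValueError(f"inconsistent counts for {sym}")


@dataclass(frozen=True)
class PmiScore:
    symbol: str
    pmi: float
    n_x: int
    n_xd: int


def curate_corpus(
    records: Sequence[AbstractRecord],
    keywords: Sequence[str],
    year_min: int,
    year_max: int,
    exclusion_terms: Sequence[str] = (),
) -> CurationReport:
    """Filter a corpus by year range, keyword inclusion and exclusion terms.

    A record is retained iff its year lies in ``[year_min, year_max]``, at
    least one keyword occurs (case-insensitive substring of title or body;
    an empty keyword list is vacuously satisfied), and no exclusion term
    occurs.  Input order is preserved and duplicate record ids collapse to
    the first occurrence.  Records missing an id or body are skipped and
    counted in the report rather than raising.
    """
    kw = [k.lower() for k in keywords]
    excl = [e.lower() for e in exclusion_terms]
    seen: set[str] = set()
    kept: list[AbstractRecord] = []
    n_malformed = n_dup = 0
    for rec in records:
        if not rec.record_id or not rec.body:
            n_malformed += 1
            continue
        if rec.record_id in seen:
            n_dup += 1
            continue
        seen.add(rec.record_id)
        if not (year_min <= rec.year <= year_max):
            continue
        text = (rec.title + "\n" + rec.body).lower()
        if kw and not any(k in text for k in kw):
            continue
        if any(e in text for e in excl):
            continue
        kept.append(rec)
    return CurationReport(kept, len(records), n_malformed, n_dup)


def _boundary_pattern(form: str) -> re.Pattern[str]:
    # word boundary = non-alphanumeric neighbour or string edge; hyphens
    # count as boundaries, so "BDNF-dependent" yields a BDNF hit
    return re.compile(
        rf"(?<![A-Za-z0-9]){re.escape(form)}(?![A-Za-z0-9])", re.IGNORECASE
    )


def match_mentions(record: AbstractRecord, lexicon: GeneLexicon) -> list[MentionHit]:
    """Tag gene/protein mentions in one abstract.

    Matching is effectively case-insensitive (both text and lexicon
    uppercased), respects word boundaries, never emits blocklisted tokens,
    and resolves overlaps longest-match-first; hits come back sorted by
    start offset.
    """
    text = record.title + "\n" + record.body
    if not text.strip():
        return []
    candidates: list[tuple[int, int, str, str]] = []
    for form, symbol in lexicon.surface_forms().items():
        for m in _boundary_pattern(form).finditer(text):
            candidates.append((m.start(), m.end(), symbol, m.group(0)))
    # longest match wins at any position; then left-to-right greedy
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
    hits: list[MentionHit] = []
    last_end = -1
    for start, end, symbol, surface in candidates:
        if start < last_end:
            continue
        hits.append(MentionHit(record.record_id, symbol, start, end, surface))
        last_end = end
    return hits


def count_cooccurrence(
    hits_by_record: Mapping[str, Iterable[MentionHit]],
    disease_record_ids: Iterable[str],
    n_docs: int,
) -> CooccurrenceCounts:
    """Collapse mention hits to per-document co-occurrence counts.

    ``disease_record_ids`` is the set of curated abstracts matching the
    disease term set; ``n_docs`` is the curated-corpus size N.
    """
    if n_docs < 1:
        raise ValueError("empty corpus")
    disease_docs = set(disease_record_ids)
    docs_by_symbol: dict[str, set[str]] = {}
    for rid, hits in hits_by_record.items():
        for h in hits:
            docs_by_symbol.setdefault(h.symbol, set()).add(rid)
    doc_count = {s: len(d) for s, d in docs_by_symbol.items()}
    joint = {s: len(d & disease_docs) for s, d in docs_by_symbol.items()}
    return CooccurrenceCounts(n_docs, doc_count, len(disease_docs), joint)


def compute_pmi(
    counts: CooccurrenceCounts, symbol: str, continuity: bool = False
) -> PmiScore:
    """Document-level PMI (log base 2) of a symbol with the disease terms.

    Zero joint count yields ``-inf`` by default (no co-occurrence evidence);
    with ``continuity=True`` an add-0.5 correction is applied to ``n_xd``
    instead.
    """
    if symbol not in counts.doc_count:
        raise KeyError(f"unknown symbol {symbol!r}")
    n_x = counts.doc_count[symbol]
    if n_x == 0:
        raise ValueError(f"symbol {symbol!r} has zero document count")
    if counts.disease_doc_count < 1:
        raise ValueError("no disease-matching documents")
    n_xd = counts.joint_count.get(symbol, 0)
    if n_xd == 0 and not continuity:
        pmi = float("-inf")
    else:
        eff = n_xd + 0.5 if (n_xd == 0 and continuity) else n_xd
        pmi = math.log2(eff * counts.n_docs / (n_x * counts.disease_doc_count))
    return PmiScore(symbol, pmi, n_x, n_xd)


def rank_proteins(
    scores: Iterable[PmiScore],
    min_pmi: float = float("-inf"),
    min_docs: int = 1,
) -> list[PmiScore]:
    """Deduplicate, threshold and order PMI scores.

    Symbols with ``pmi = -inf`` (zero joint count sentinel) are always
    excluded.  Order: pmi descending, then symbol ascending — deterministic.
    """
    best: dict[str, PmiScore] = {}
    for s in scores:
        if s.symbol not in best or s.pmi > best[s.symbol].pmi:
            best[s.symbol] = s
    kept = [
        s
        for s in best.values()
        if s.pmi >= min_pmi and s.n_x >= min_docs and not math.isinf(s.pmi)
    ]
    return sorted(kept, key=lambda s: (-s.pmi, s.symbol))


# ---------------------------------------------------------------------------
# I/O: MEDLINE flat file, line-delimited structured dialect, lexicon TSV
# ---------------------------------------------------------------------------

def _year_of(dp: str) -> int:
    m = re.search(r"\b(\d{4})\b", dp or "")
    return int(m.group(1)) if m else 0


def read_medline(path: str | Path) -> list[AbstractRecord]:
    """Read a MEDLINE flat file (PMID/TI/AB/DP tags)."""
    with open(path, encoding="utf-8") as fh:
        return [
            AbstractRecord(
                record_id=rec.get("PMID", ""),
                title=rec.get("TI", ""),
                body=rec.get("AB", ""),
                year=_year_of(rec.get("DP", "")),
            )
            for rec in Medline.parse(fh)
        ]


def read_structured(path: str | Path) -> list[AbstractRecord]:
    """Read the line-delimited dialect: id<TAB>year<TAB>title<TAB>body."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{i}: expected 4 tab-separated fields")
            rid, year, title, body = parts
            records.append(AbstractRecord(rid, title, body, int(year)))
    return records


def write_structured(records: Iterable[AbstractRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.record_id}\t{r.year}\t{r.title}\t{r.body}\n")


def read_lexicon(path: str | Path, **kwargs) -> GeneLexicon:
    """Read a lexicon TSV: columns symbol, synonyms (pipe-separated),
    optional ``blocked`` flag."""
    entries: dict[str, list[str]] = {}
    blocklist: list[str] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        if "symbol" not in idx:
            raise ValueError(f"{path}: missing 'symbol' column")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            symbol = parts[idx["symbol"]]
            syns = []
            if "synonyms" in idx and len(parts) > idx["synonyms"]:
                syns = [s for s in parts[idx["synonyms"]].split("|") if s]
            blocked = (
                "blocked" in idx
                and len(parts) > idx["blocked"]
                and parts[idx["blocked"]].strip().lower() in ("1", "true", "yes")
            )
            if blocked:
                blocklist.extend([symbol, *syns])
            else:
                entries[symbol] = syns
    return GeneLexicon(entries, blocklist=blocklist, **kwargs)


def write_pmi_table(
    scores: Iterable[PmiScore], n_docs: int, path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("symbol\tpmi\tn_x\tn_xd\tn_docs\n")
        for s in scores:
            fh.write(f"{s.symbol}\t{s.pmi:.6g}\t{s.n_x}\t{s.n_xd}\t{n_docs}\n")
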