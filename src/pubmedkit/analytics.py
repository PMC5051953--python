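"""Corpus statistics over citation stores, search hits, and entity mentions.

The entity-mention side consumes the tab-separated files that named-entity
recognisers emit — one mention per line: PubMed ID, synonym (surface form),
normalised identifier (e.g. an Entrez GeneID, a MeSH/MEDIC disease id, a
DrugBank id), and optionally an entity type.  Counting is per *abstract*:
an identifier's count is the number of distinct PMIDs it was found in, no
matter how often it was mentioned inside one abstract.  Mentions lacking an
identifier (normalisation can fail) are grouped under their surface form.

On top of that sit word-cloud weights (top-k identifiers, counts scaled to
a maximum of 1.0), identifier merging (e.g. summarising organism-specific
Entrez GeneIDs of one gene before counting), publication-year timelines,
whitespace-tokeniser term frequencies, and an HTML report of ranked search
hits with highlighted query terms.
"""

from __future__ import annotations

import csv
import html
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .index import SearchHit, tokenize
from .storage import Store

logger = logging.getLogger(__name__)

__all__ = [
    "EntityMention",
    "EntityCount",
    "read_mentions_tsv",
    "count_entities",
    "top_k_weights",
    "merge_identifiers",
    "timeline",
    "term_frequencies",
    "highlight_report",
]


@dataclass(frozen=True)
class EntityMention:
    """One row of a mention TSV: a surface form found in one abstract."""

    pmid: int
    synonym: str
    identifier: str = ""
    entity_type: str = ""

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError(f"pmid must be positive, got {self.pmid}")

    @property
    def group_key(self) -> str:
        """Identifier when normalised, else the surface form."""
        return self.identifier if self.identifier else self.synonym


@dataclass(frozen=True)
class EntityCount:
    """One aggregated row: identifier, representative synonym, abstract count."""

    identifier: str
    synonym: str
    count: int
    pmids: frozenset[int]


def read_mentions_tsv(source: str | Path | IO[str]) -> list[EntityMention]:
    """Read a mention TSV (pmid, synonym, identifier[, type]; no header).

    Malformed rows are skipped with a warning naming the line number.
    """
    if isinstance(source, (str, Path)):
        handle: IO[str] = open(source, encoding="utf-8", newline="")
        close = True
    else:
        handle, close = source, False
    mentions = []
    try:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2 or not row[0].strip().isdigit():
                logger.warning("skipping malformed mention row at line %d", lineno)
                continue
            mentions.append(
                EntityMention(
                    pmid=int(row[0]),
                    synonym=row[1].strip(),
                    identifier=row[2].strip() if len(row) > 2 else "",
                    entity_type=row[3].strip() if len(row) > 3 else "",
                )
            )
    finally:
        if close:
            handle.close()
    return mentions


def count_entities(mentions: Iterable[EntityMention]) -> list[EntityCount]:
    """Count abstracts per entity by summarising synonyms per identifier.

    Mentions are grouped by identifier (surface form when the identifier is
    empty); the count is the number of distinct PMIDs in the group.  The
    representative synonym is the group's most frequent surface form, ties
    broken lexicographically.  Rows are sorted by count descending, then
    identifier ascending.
    """
    pmid_sets: dict[str, set[int]] = {}
    synonym_freq: dict[str, dict[str, int]] = {}
    for mention in mentions:
        key = mention.group_key
        pmid_sets.setdefault(key, set()).add(mention.pmid)
        freq = synonym_freq.setdefault(key, {})
        freq[mention.synonym] = freq.get(mention.synonym, 0) + 1
    rows = []
    for key, pmids in pmid_sets.items():
        freq = synonym_freq[key]
        representative = min(freq, key=lambda s: (-freq[s], s))
        rows.append(
            EntityCount(
                identifier=key,
                synonym=representative,
                count=len(pmids),
                pmids=frozenset(pmids),
            )
        )
    rows.sort(key=lambda r: (-r.count, r.identifier))
    return rows


def top_k_weights(
    table: Sequence[EntityCount], k: int = 150
) -> list[tuple[str, float]]:
    """Top-k entities with counts normalised to a maximum weight of 1.0.

    The default k of 150 matches the usual word-cloud size.  Returned as
    (representative synonym, weight) pairs, weight in (0, 1], first = 1.0.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    top = list(table[:k])
    if not top:
        return []
    max_count = top[0].count
    return [(row.synonym, row.count / max_count) for row in top]


def merge_identifiers(
    table: Sequence[EntityCount], groups: Mapping[str, Iterable[str]]
) -> list[EntityCount]:
    """Merge identifier groups into single concepts before counting.

    ``groups`` maps a concept name to the identifiers it summarises (e.g.
    one gene symbol to its organism-specific Entrez GeneIDs).  Groups must
    be disjoint.  Each group's PMID sets are unioned, so the merged count is
    the size of the union, not the sum.
    """
    normalized = {name: set(ids) for name, ids in groups.items()}
    seen: set[str] = set()
    for name, ids in normalized.items():
        overlap = seen & ids
        if overlap:
            raise ValueError(f"identifier groups overlap on {sorted(overlap)}")
        seen |= ids
    by_id = {row.identifier: row for row in table}
    rows = []
    consumed: set[str] = set()
    for name, ids in normalized.items():
        members = [by_id[i] for i in ids if i in by_id]
        if not members:
            continue
        consumed |= {m.identifier for m in members}
        pmids = frozenset().union(*(m.pmids for m in members))
        rows.append(
            EntityCount(identifier=name, synonym=name, count=len(pmids), pmids=pmids)
        )
    rows.extend(row for row in table if row.identifier not in consumed)
    rows.sort(key=lambda r: (-r.count, r.identifier))
    return rows


def timeline(
    mentions: Iterable[EntityMention],
    identifiers: Iterable[str],
    store: Store,
) -> tuple[dict[int, int], set[int]]:
    """Publication-year counts for the abstracts mentioning a concept group.

    The distinct PMIDs carrying any of ``identifiers`` are looked up in the
    store; the result maps every year in the observed range to its count
    (zero-filled inside the range).  PMIDs without a stored year are
    returned separately.
    """
    wanted = set(identifiers)
    pmids = {m.pmid for m in mentions if m.group_key in wanted}
    years, missing = store.years_of(pmids)
    if years:
        lo, hi = min(years), max(years)
        years = {year: years.get(year, 0) for year in range(lo, hi + 1)}
    return years, missing


def term_frequencies(
    store: Store, pmids: Iterable[int]
) -> list[tuple[str, int]]:
    """Token frequencies over the titles and abstracts of a PMID set.

    Uses the index's whitespace tokeniser (punctuation stripped, lowercase).
    Sorted by frequency descending, ties by token ascending.
    """
    counts: dict[str, int] = {}
    for pmid in sorted(set(pmids)):
        citation = store.get(pmid)
        if citation is None:
            continue
        text = citation.title
        if citation.abstract:
            text += " " + citation.abstract
        for token in tokenize(text):
            counts[token.surface] = counts.get(token.surface, 0) + 1
    return sorted(counts.items(), key=lambda item: (-item[1], item[0]))


# ---------------------------------------------------------------------------
# Highlighted search report
# ---------------------------------------------------------------------------

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Search results</title>
<style>
table {{ border-collapse: collapse; }}
th, td {{ border: 1px solid #999; padding: 4px 8px; vertical-align: top; }}
mark {{ background: #ffec8b; }}
</style>
</head>
<body>
<h1>Search results</h1>
<p>{caption}</p>
<table>
<tr><th>Rank</th><th>Score</th><th>PMID</th><th>Title</th><th>Abstract</th></tr>
{rows}
</table>
</body>
</html>
"""


def _highlight(text: str, terms: Sequence[str]) -> str:
    """HTML-escape text and wrap term occurrences in <mark> elements.

    Matching is case-insensitive, non-overlapping, leftmost match first
    (longer terms win on ties at the same position).
    """
    if not terms:
        return html.escape(text)
    pattern = re.compile(
        "|".join(re.escape(t) for t in sorted(terms, key=len, reverse=True) if t),
        re.IGNORECASE,
    )
    out = []
    pos = 0
    for match in pattern.finditer(text):
        out.append(html.escape(text[pos : match.start()]))
        out.append(f"<mark>{html.escape(match.group(0))}</mark>")
        pos = match.end()
    out.append(html.escape(text[pos:]))
    return "".join(out)


def highlight_report(
    hits: Sequence[SearchHit],
    store: Store,
    highlight_terms: Sequence[str],
    caption: str = "",
) -> str:
    """Render ranked search hits as an HTML page with highlighted terms.

    One row per hit: 1-based rank, relevance score (top hit 100), PMID, and
    the title/abstract with every case-insensitive occurrence of each
    highlight term wrapped in a ``<mark>`` element.  Returns the HTML text.
    """
    rows = []
    for rank, hit in enumerate(hits, start=1):
        citation = store.get(hit.pmid)
        title = citation.title if citation else ""
        abstract = (citation.abstract or "") if citation else ""
        rows.append(
            "<tr><td>{rank}</td><td>{score:.1f}</td><td>{pmid}</td>"
            "<td>{title}</td><td>{abstract}</td></tr>".format(
                rank=rank,
                score=hit.score,
                pmid=hit.pmid,
                title=_highlight(title, highlight_terms),
                abstract=_highlight(abstract, highlight_terms),
            )
        )
    return _PAGE.format(caption=html.escape(caption), rows="\n".join(rows))
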