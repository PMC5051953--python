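"""Positional full-text index with Boolean, phrase, and proximity search.

Citations are tokenised with a whitespace tokeniser that strips surrounding
punctuation and lowercases (internal punctuation such as the hyphen in
``CA19-9`` is kept).  The index records, per term, every (document, field)
pair and the 0-based word positions inside that field, which is what phrase
and NEAR/k evaluation need.  Two field sets are supported:

* ``full`` — title, abstract, MeSH descriptor names, keywords, and chemical
  substance names;
* ``titles_abstracts_only`` — the reduced variant indexing only the title
  and abstract.

Queries are an AST over :class:`Term`, :class:`And`, :class:`Or`,
:class:`AndNot`, :class:`Phrase`, and :class:`Near`.  ``Near(a, b, k)``
matches when both operands occur in the same field with at most ``k``
intervening words, in either order (``|pos(a) - pos(b)| <= k + 1``).  Each
field of a document is an independent position space: phrase and proximity
matches never cross field boundaries.

Hits are ranked by a BM25 weight (k1=1.2, b=0.75) summed over the query's
positive terms and min-max scaled so the best hit scores exactly 100; ties
are broken by PMID ascending.  A small query-string language is provided for
the command line: ``erlotinib NEAR/4 "pancreatic cancer" AND gemcitabine``.
"""

from __future__ import annotations

import json
import math
import re
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .storage import Store

__all__ = [
    "Token",
    "tokenize",
    "FULL_FIELDS",
    "REDUCED_FIELDS",
    "PositionalIndex",
    "build_index",
    "Query",
    "Term",
    "And",
    "Or",
    "AndNot",
    "Phrase",
    "Near",
    "SearchHit",
    "search",
    "phrase_search",
    "parse_query",
    "QuerySyntaxError",
]

_PUNCT = string.punctuation + "‘’“”–—"

FULL_FIELDS: tuple[str, ...] = ("title", "abstract", "mesh", "keyword", "chemical")
REDUCED_FIELDS: tuple[str, ...] = ("title", "abstract")

_FIELDSETS: dict[str, tuple[str, ...]] = {
    "full": FULL_FIELDS,
    "titles_abstracts_only": REDUCED_FIELDS,
}


@dataclass(frozen=True)
class Token:
    surface: str
    position: int


def tokenize(text: str) -> list[Token]:
    """Whitespace tokenisation with punctuation stripping.

    Pieces are split on whitespace, stripped of leading/trailing punctuation,
    lowercased, and dropped if nothing remains; surviving tokens are numbered
    from 0.
    """
    tokens: list[Token] = []
    for piece in text.split():
        word = piece.strip(_PUNCT).lower()
        if word:
            tokens.append(Token(word, len(tokens)))
    return tokens


def _terms(text: str) -> list[str]:
    return [t.surface for t in tokenize(text)]


# ---------------------------------------------------------------------------
# Query AST
# ---------------------------------------------------------------------------


class Query:
    """Base class for query AST nodes."""

    __slots__ = ()


@dataclass(frozen=True)
class Term(Query):
    text: str

    def __post_init__(self) -> None:
        if not self.text or any(c.isspace() for c in self.text):
            raise ValueError(f"invalid term: {self.text!r}")


@dataclass(frozen=True)
class And(Query):
    left: Query
    right: Query


@dataclass(frozen=True)
class Or(Query):
    left: Query
    right: Query


@dataclass(frozen=True)
class AndNot(Query):
    left: Query
    right: Query


@dataclass(frozen=True)
class Phrase(Query):
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.terms) < 1:
            raise ValueError("phrase must contain at least one term")


@dataclass(frozen=True)
class Near(Query):
    """Proximity: operands in one field with <= k intervening words, unordered.

    Operands must be positional (Term or Phrase); a phrase's position is the
    position of its first token.
    """

    left: Query
    right: Query
    k: int

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        for operand in (self.left, self.right):
            if not isinstance(operand, (Term, Phrase)):
                raise ValueError("Near operands must be Term or Phrase")


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------

#: A field instance key: (field name, occurrence index) — e.g. the second
#: keyword of a record is ("keyword", 1).  Each instance is its own position
#: space.
FieldKey = tuple[str, int]


class PositionalIndex:
    """Term -> {(pmid, field instance) -> sorted positions} postings."""

    def __init__(self, fieldset: str) -> None:
        if fieldset not in _FIELDSETS:
            raise ValueError(
                f"fieldset must be one of {sorted(_FIELDSETS)}, got {fieldset!r}"
            )
        self.fieldset = fieldset
        self.fields = _FIELDSETS[fieldset]
        self.postings: dict[str, dict[tuple[int, FieldKey], list[int]]] = {}
        self.doc_lengths: dict[int, int] = {}

    # -- construction ------------------------------------------------------

    def add_document(self, pmid: int, fields: Iterable[tuple[FieldKey, str]]) -> None:
        length = 0
        for field_key, text in fields:
            for token in tokenize(text):
                self.postings.setdefault(token.surface, {}).setdefault(
                    (pmid, field_key), []
                ).append(token.position)
                length += 1
        self.doc_lengths[pmid] = self.doc_lengths.get(pmid, 0) + length

    # -- stats -------------------------------------------------------------

    @property
    def n_docs(self) -> int:
        return len(self.doc_lengths)

    def doc_freq(self, term: str) -> int:
        entry = self.postings.get(term)
        if not entry:
            return 0
        return len({pmid for pmid, _ in entry})

    def term_freq(self, term: str, pmid: int) -> int:
        entry = self.postings.get(term)
        if not entry:
            return 0
        return sum(len(pos) for (p, _), pos in entry.items() if p == pmid)

    def occurrences(self, term: str) -> dict[tuple[int, FieldKey], list[int]]:
        return self.postings.get(term, {})

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist to a JSON file next to the store."""
        payload = {
            "fieldset": self.fieldset,
            "doc_lengths": {str(p): n for p, n in self.doc_lengths.items()},
            "postings": {
                term: [
                    [pmid, field, occ, positions]
                    for (pmid, (field, occ)), positions in entry.items()
                ]
                for term, entry in self.postings.items()
            },
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def open(cls, path: str | Path) -> "PositionalIndex":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        index = cls(payload["fieldset"])
        index.doc_lengths = {int(p): n for p, n in payload["doc_lengths"].items()}
        index.postings = {
            term: {
                (pmid, (field, occ)): positions
                for pmid, field, occ, positions in entry
            }
            for term, entry in payload["postings"].items()
        }
        return index


def _citation_fields(
    citation, fieldset: tuple[str, ...]
) -> Iterator[tuple[FieldKey, str]]:
    if "title" in fieldset:
        yield ("title", 0), citation.title
    if "abstract" in fieldset and citation.abstract:
        yield ("abstract", 0), citation.abstract
    if "mesh" in fieldset:
        for i, heading in enumerate(citation.mesh_headings):
            yield ("mesh", i), heading.descriptor_name
    if "keyword" in fieldset:
        for i, keyword in enumerate(citation.keywords):
            yield ("keyword", i), keyword
    if "chemical" in fieldset:
        for i, substance in enumerate(citation.chemicals):
            yield ("chemical", i), substance


def build_index(store: Store, fieldset: str = "full") -> PositionalIndex:
    """Index every citation of a store over the requested field set."""
    index = PositionalIndex(fieldset)
    for citation in store.citations():
        index.add_document(citation.pmid, _citation_fields(citation, index.fields))
    return index


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _positional_occurrences(
    index: PositionalIndex, node: Query
) -> dict[tuple[int, FieldKey], list[int]]:
    """Occurrence positions for a positional node (Term or Phrase).

    A phrase occurrence is located at its first token's position.
    """
    if isinstance(node, Term):
        return index.occurrences(node.text.lower())
    if isinstance(node, Phrase):
        first = index.occurrences(node.terms[0])
        result: dict[tuple[int, FieldKey], list[int]] = {}
        for key, starts in first.items():
            rest = [set(index.occurrences(t).get(key, ())) for t in node.terms[1:]]
            matches = [
                s for s in starts if all(s + i + 1 in positions
                                         for i, positions in enumerate(rest))
            ]
            if matches:
                result[key] = matches
        return result
    raise TypeError(f"not a positional node: {node!r}")


def _eval(index: PositionalIndex, node: Query) -> set[int]:
    if isinstance(node, (Term, Phrase)):
        return {pmid for pmid, _ in _positional_occurrences(index, node)}
    if isinstance(node, And):
        return _eval(index, node.left) & _eval(index, node.right)
    if isinstance(node, Or):
        return _eval(index, node.left) | _eval(index, node.right)
    if isinstance(node, AndNot):
        return _eval(index, node.left) - _eval(index, node.right)
    if isinstance(node, Near):
        left = _positional_occurrences(index, node.left)
        right = _positional_occurrences(index, node.right)
        hits: set[int] = set()
        for key, left_positions in left.items():
            pmid = key[0]
            if pmid in hits:
                continue
            right_positions = right.get(key)
            if not right_positions:
                continue
            if any(
                abs(a - b) <= node.k + 1
                for a in left_positions
                for b in right_positions
            ):
                hits.add(pmid)
        return hits
    raise TypeError(f"unknown query node: {node!r}")


def _positive_terms(node: Query) -> set[str]:
    """Terms that positively select hits (the excluded branch of AndNot
    contributes nothing to relevance)."""
    if isinstance(node, Term):
        return {node.text.lower()}
    if isinstance(node, Phrase):
        return set(node.terms)
    if isinstance(node, (And, Or)):
        return _positive_terms(node.left) | _positive_terms(node.right)
    if isinstance(node, AndNot):
        return _positive_terms(node.left)
    if isinstance(node, Near):
        return _positive_terms(node.left) | _positive_terms(node.right)
    raise TypeError(f"unknown query node: {node!r}")


_BM25_K1 = 1.2
_BM25_B = 0.75


def _bm25(index: PositionalIndex, terms: set[str], pmid: int) -> float:
    n = index.n_docs
    if n == 0:
        return 0.0
    avgdl = sum(index.doc_lengths.values()) / n
    dl = index.doc_lengths.get(pmid, 0)
    score = 0.0
    for term in terms:
        tf = index.term_freq(term, pmid)
        if tf == 0:
            continue
        df = index.doc_freq(term)
        idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
        denom = tf + _BM25_K1 * (1.0 - _BM25_B + _BM25_B * dl / avgdl) if avgdl else tf
        score += idf * tf * (_BM25_K1 + 1.0) / denom
    return score


@dataclass(frozen=True)
class SearchHit:
    pmid: int
    score: float


def search(index: PositionalIndex, query: Query, limit: int = 10) -> list[SearchHit]:
    """Evaluate a query and rank its hits with the top score scaled to 100.

    The hit set follows the exact Boolean/positional semantics of the AST;
    scores are the BM25 weight of the query's positive terms, scaled so the
    best hit is exactly 100 and all hits are > 0.  Ties break by PMID
    ascending.
    """
    if query is None:
        raise ValueError("query must be non-empty")
    if limit < 1:
        raise ValueError(f"limit must be >= 1, got {limit}")
    hit_pmids = _eval(index, query)
    if not hit_pmids:
        return []
    terms = _positive_terms(query)
    raw = {pmid: _bm25(index, terms, pmid) for pmid in hit_pmids}
    top = max(raw.values())
    if top <= 0.0:  # degenerate (e.g. empty positive-term set); rank flat
        scaled = {pmid: 100.0 for pmid in raw}
    else:
        # divide first so ties at the maximum scale to exactly 100.0
        scaled = {pmid: min(100.0, (s / top) * 100.0) for pmid, s in raw.items()}
    ranked = sorted(scaled.items(), key=lambda item: (-item[1], item[0]))
    return [SearchHit(pmid, score) for pmid, score in ranked[:limit]]


def phrase_search(
    index: PositionalIndex, phrase: str, limit: int = 10
) -> list[SearchHit]:
    """Search for an exact phrase given as free text.

    Sugar for ``search(Phrase(tokenize(phrase)))``; a single-word phrase is
    equivalent to a Term query.
    """
    terms = _terms(phrase)
    if not terms:
        raise ValueError("phrase must contain at least one token")
    return search(index, Phrase(tuple(terms)), limit)


# ---------------------------------------------------------------------------
# Query-string mini-language
# ---------------------------------------------------------------------------


class QuerySyntaxError(ValueError):
    """Raised when a query string cannot be parsed."""


_TOKEN_RE = re.compile(
    r"""
    \s*(?:
        (?P<lparen>\() |
        (?P<rparen>\)) |
        (?P<phrase>"[^"]*") |
        (?P<near>NEAR/(?P<k>\d+)) |
        (?P<and>AND\b) |
        (?P<or>OR\b) |
        (?P<not>NOT\b) |
        (?P<word>[^\s()"]+)
    )
    """,
    re.VERBOSE,
)


def _lex(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None or match.end() == pos:
            if text[pos:].strip():
                raise QuerySyntaxError(f"cannot tokenize query at: {text[pos:]!r}")
            break
        pos = match.end()
        kind = match.lastgroup if match.lastgroup != "k" else "near"
        for name in ("lparen", "rparen", "phrase", "near", "and", "or", "not", "word"):
            if match.group(name):
                value = match.group("k") if name == "near" else match.group(name)
                tokens.append((name, value))
                break
    return tokens


class _Parser:
    """Recursive descent: OR < AND/NOT < NEAR/k < atom."""

    def __init__(self, tokens: list[tuple[str, str]]) -> None:
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, str]:
        token = self.peek()
        if token is None:
            raise QuerySyntaxError("unexpected end of query")
        self.pos += 1
        return token

    def parse(self) -> Query:
        node = self.or_expr()
        if self.peek() is not None:
            raise QuerySyntaxError(f"unexpected token: {self.peek()[1]!r}")
        return node

    def or_expr(self) -> Query:
        node = self.and_expr()
        while self.peek() and self.peek()[0] == "or":
            self.take()
            node = Or(node, self.and_expr())
        return node

    def and_expr(self) -> Query:
        node = self.near_expr()
        while self.peek() and self.peek()[0] in ("and", "not"):
            kind, _ = self.take()
            right = self.near_expr()
            node = And(node, right) if kind == "and" else AndNot(node, right)
        return node

    def near_expr(self) -> Query:
        node = self.atom()
        while self.peek() and self.peek()[0] == "near":
            _, k = self.take()
            right = self.atom()
            node = Near(node, right, int(k))
        return node

    def atom(self) -> Query:
        kind, value = self.take()
        if kind == "lparen":
            node = self.or_expr()
            if self.peek() is None or self.take()[0] != "rparen":
                raise QuerySyntaxError("unbalanced parenthesis")
            return node
        if kind == "phrase":
            terms = _terms(value[1:-1])
            if not terms:
                raise QuerySyntaxError("empty phrase")
            return Phrase(tuple(terms))
        if kind == "word":
            terms = _terms(value)
            if not terms:
                raise QuerySyntaxError(f"term reduces to nothing: {value!r}")
            return Term(terms[0])
        raise QuerySyntaxError(f"unexpected token: {value!r}")


def parse_query(text: str) -> Query:
    """Parse the CLI query language into a Query AST.

    Grammar (loosest to tightest binding): ``OR``; ``AND`` / ``NOT``
    (set difference); ``NEAR/k``; atoms are bare words, quoted phrases, and
    parenthesised sub-queries.  Example::

        erlotinib NEAR/4 "pancreatic cancer" AND gemcitabine
    """
    tokens = _lex(text)
    if not tokens:
        raise QuerySyntaxError("empty query")
    return _Parser(tokens).parse()
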