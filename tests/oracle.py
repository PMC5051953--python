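"""Brute-force oracles, independent of the package's index implementation.

Everything here works by linear scans over ground-truth Citation lists using
its own tokenizer, so it can serve as the reference for the inverted index,
the ranked store queries, and the entity statistics.
"""

from __future__ import annotations

import string

from pubmedkit.index import And, AndNot, Near, Or, Phrase, Query, Term

_PUNCT = string.punctuation + "‘’“”–—"


def oracle_tokens(text: str) -> list[str]:
    """Whitespace split, strip surrounding punctuation, lowercase."""
    return [w for w in (p.strip(_PUNCT).lower() for p in text.split()) if w]


def citation_fields(citation, fieldset: str) -> list[list[str]]:
    """Token lists of every indexed field instance of one citation."""
    fields = [oracle_tokens(citation.title)]
    if citation.abstract:
        fields.append(oracle_tokens(citation.abstract))
    if fieldset == "full":
        fields.extend(oracle_tokens(h.descriptor_name) for h in citation.mesh_headings)
        fields.extend(oracle_tokens(k) for k in citation.keywords)
        fields.extend(oracle_tokens(c) for c in citation.chemicals)
    return fields


def _positions(node: Query, tokens: list[str]) -> list[int]:
    """Occurrence positions of a positional node within one field."""
    if isinstance(node, Term):
        term = node.text.lower()
        return [i for i, w in enumerate(tokens) if w == term]
    if isinstance(node, Phrase):
        terms = list(node.terms)
        return [
            i
            for i in range(len(tokens) - len(terms) + 1)
            if tokens[i : i + len(terms)] == terms
        ]
    raise TypeError(node)


def matches(node: Query, citation, fieldset: str) -> bool:
    fields = citation_fields(citation, fieldset)
    if isinstance(node, (Term, Phrase)):
        return any(_positions(node, f) for f in fields)
    if isinstance(node, And):
        return matches(node.left, citation, fieldset) and matches(
            node.right, citation, fieldset
        )
    if isinstance(node, Or):
        return matches(node.left, citation, fieldset) or matches(
            node.right, citation, fieldset
        )
    if isinstance(node, AndNot):
        return matches(node.left, citation, fieldset) and not matches(
            node.right, citation, fieldset
        )
    if isinstance(node, Near):
        for f in fields:
            left = _positions(node.left, f)
            right = _positions(node.right, f)
            if any(abs(a - b) <= node.k + 1 for a in left for b in right):
                return True
        return False
    raise TypeError(node)


def oracle_hits(query: Query, citations, fieldset: str = "full") -> set[int]:
    return {c.pmid for c in citations if matches(query, c, fieldset)}


def oracle_journal_counts(citations, descriptor: str) -> list[tuple[str, int]]:
    """Distinct-pmid counts per journal for one MeSH descriptor, ranked."""
    counts: dict[str, set[int]] = {}
    for c in citations:
        if c.journal_ta is None:
            continue
        if any(h.descriptor_name == descriptor for h in c.mesh_headings):
            counts.setdefault(c.journal_ta, set()).add(c.pmid)
    ranked = [(journal, len(pmids)) for journal, pmids in counts.items()]
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked
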