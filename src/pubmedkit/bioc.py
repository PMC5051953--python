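"""BioC XML interchange: data model, reader/writer, exporter, annotators.

BioC is a minimalistic XML format for exchanging text and annotations
between text-mining tools: a ``collection`` (with its creation ``source``,
``date``, and the name of a ``key`` file describing the semantics used)
holds ``document`` elements; a document holds ``passage`` elements (here:
the citation title and, when present, the abstract); passages carry
``annotation`` elements with an ``offset``/``length`` location and the
annotated surface ``text``.  Arbitrary metadata travels in ``infon``
key/value elements at every level.

Conventions used throughout:

* offsets are 0-based *character* offsets into the document text (the
  concatenation of passage texts), half-open ``[offset, offset + length)``;
* the abstract passage starts at ``len(title) + 1`` — one separator
  character between passages;
* every annotation must satisfy the substring invariant: the document text
  at its location equals its ``text``.  Writers validate this before
  emitting XML.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from lxml import etree

from .storage import Store

__all__ = [
    "BioCLocation",
    "BioCAnnotation",
    "BioCPassage",
    "BioCDocument",
    "BioCCollection",
    "BioCFormatError",
    "BioCValidationError",
    "read_bioc",
    "write_bioc",
    "export_bioc",
    "annotate_mesh",
    "merge_annotations",
]

PASSAGE_SEPARATOR = " "  # one character between consecutive passages


class BioCFormatError(ValueError):
    """Input XML does not follow the BioC element structure."""


class BioCValidationError(ValueError):
    """A collection violates a BioC invariant (e.g. annotation substring)."""


@dataclass(frozen=True)
class BioCLocation:
    offset: int
    length: int

    def __post_init__(self) -> None:
        if self.offset < 0 or self.length < 0:
            raise ValueError("offset and length must be non-negative")


@dataclass(frozen=True)
class BioCAnnotation:
    id: str
    infons: tuple[tuple[str, str], ...]
    location: BioCLocation
    text: str

    def __post_init__(self) -> None:
        if self.location.length != len(self.text):
            raise ValueError(
                f"annotation {self.id!r}: length {self.location.length} != "
                f"character count of text ({len(self.text)})"
            )

    @property
    def infon_map(self) -> dict[str, str]:
        return dict(self.infons)


@dataclass(frozen=True)
class BioCPassage:
    infons: tuple[tuple[str, str], ...]
    offset: int
    text: str
    annotations: tuple[BioCAnnotation, ...] = ()

    @property
    def infon_map(self) -> dict[str, str]:
        return dict(self.infons)


@dataclass(frozen=True)
class BioCDocument:
    id: str
    passages: tuple[BioCPassage, ...] = ()
    infons: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("document id must be non-empty")

    def text(self) -> str:
        """Document text reconstructed from passages at their offsets.

        Gaps between passages are filled with the separator character.
        """
        if not self.passages:
            return ""
        end = max(p.offset + len(p.text) for p in self.passages)
        chars = [PASSAGE_SEPARATOR] * end
        for passage in self.passages:
            for i, ch in enumerate(passage.text):
                chars[passage.offset + i] = ch
        return "".join(chars)

    def annotations(self) -> tuple[BioCAnnotation, ...]:
        return tuple(a for p in self.passages for a in p.annotations)


@dataclass(frozen=True)
class BioCCollection:
    source: str
    date: str
    key: str
    documents: tuple[BioCDocument, ...] = ()
    infons: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.source or not self.date:
            raise ValueError("collection must carry source and date")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _validate_collection(collection: BioCCollection) -> None:
    for document in collection.documents:
        last_offset = -1
        for passage in document.passages:
            if passage.offset <= last_offset:
                raise BioCValidationError(
                    f"document {document.id}: passage offsets must be strictly"
                    " increasing"
                )
            last_offset = passage.offset
        text = document.text()
        for annotation in document.annotations():
            start = annotation.location.offset
            end = start + annotation.location.length
            if end > len(text) or text[start:end] != annotation.text:
                raise BioCValidationError(
                    f"document {document.id}, annotation {annotation.id}:"
                    f" text {annotation.text!r} does not match document text at"
                    f" [{start}, {end})"
                )


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _read_infons(elem: etree._Element) -> tuple[tuple[str, str], ...]:
    infons = []
    for infon in elem.findall("infon"):
        key = infon.get("key")
        if key is None:
            raise BioCFormatError("infon element without key attribute")
        infons.append((key, infon.text or ""))
    return tuple(infons)


def _req_text(parent: etree._Element, tag: str, where: str) -> str:
    elem = parent.find(tag)
    if elem is None:
        raise BioCFormatError(f"missing <{tag}> element in <{where}>")
    return elem.text or ""


def read_bioc(source: str | Path | IO[bytes]) -> BioCCollection:
    """Read a BioC XML file into the in-memory collection model.

    Every infon, passage, annotation, and location is preserved.  Elements
    outside the BioC structure raise :class:`BioCFormatError` naming the
    offending element.
    """
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise BioCFormatError(f"malformed BioC XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "collection":
        raise BioCFormatError(f"expected <collection> root, found <{root.tag}>")
    documents = []
    for doc_elem in root.findall("document"):
        passages = []
        for pas_elem in doc_elem.findall("passage"):
            annotations = []
            for ann_elem in pas_elem.findall("annotation"):
                loc_elem = ann_elem.find("location")
                if loc_elem is None:
                    raise BioCFormatError("annotation without <location> element")
                annotations.append(
                    BioCAnnotation(
                        id=ann_elem.get("id", ""),
                        infons=_read_infons(ann_elem),
                        location=BioCLocation(
                            offset=int(loc_elem.get("offset", "0")),
                            length=int(loc_elem.get("length", "0")),
                        ),
                        text=_req_text(ann_elem, "text", "annotation"),
                    )
                )
            passages.append(
                BioCPassage(
                    infons=_read_infons(pas_elem),
                    offset=int(_req_text(pas_elem, "offset", "passage")),
                    text=pas_elem.findtext("text", default=""),
                    annotations=tuple(annotations),
                )
            )
        documents.append(
            BioCDocument(
                id=_req_text(doc_elem, "id", "document"),
                passages=tuple(passages),
                infons=_read_infons(doc_elem),
            )
        )
    return BioCCollection(
        source=_req_text(root, "source", "collection"),
        date=_req_text(root, "date", "collection"),
        key=root.findtext("key", default=""),
        documents=tuple(documents),
        infons=_read_infons(root),
    )


def _write_infons(parent: etree._Element, infons: Sequence[tuple[str, str]]) -> None:
    for key, value in infons:
        infon = etree.SubElement(parent, "infon", key=key)
        infon.text = value


def write_bioc(
    collection: BioCCollection,
    path: str | Path,
    key_semantics: str | None = None,
) -> Path:
    """Validate and serialize a collection to BioC XML.

    A companion ``.key`` text file describing the annotation semantics is
    written next to the output when ``key_semantics`` is given.  Violated
    invariants (passage offsets, annotation substrings) raise
    :class:`BioCValidationError` before anything is written.
    """
    _validate_collection(collection)
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = collection.source
    etree.SubElement(root, "date").text = collection.date
    etree.SubElement(root, "key").text = collection.key
    _write_infons(root, collection.infons)
    for document in collection.documents:
        doc_elem = etree.SubElement(root, "document")
        etree.SubElement(doc_elem, "id").text = document.id
        _write_infons(doc_elem, document.infons)
        for passage in document.passages:
            pas_elem = etree.SubElement(doc_elem, "passage")
            _write_infons(pas_elem, passage.infons)
            etree.SubElement(pas_elem, "offset").text = str(passage.offset)
            etree.SubElement(pas_elem, "text").text = passage.text
            for annotation in passage.annotations:
                ann_elem = etree.SubElement(pas_elem, "annotation", id=annotation.id)
                _write_infons(ann_elem, annotation.infons)
                etree.SubElement(
                    ann_elem,
                    "location",
                    offset=str(annotation.location.offset),
                    length=str(annotation.location.length),
                )
                etree.SubElement(ann_elem, "text").text = annotation.text
    path = Path(path)
    path.write_bytes(
        etree.tostring(
            etree.ElementTree(root),
            xml_declaration=True,
            encoding="UTF-8",
            pretty_print=True,
            doctype='<!DOCTYPE collection SYSTEM "BioC.dtd">',
        )
    )
    if key_semantics is not None and collection.key:
        key_path = path.parent / collection.key
        key_path.write_text(key_semantics, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Store export
# ---------------------------------------------------------------------------


def export_bioc(
    store: Store,
    pmids: Iterable[int],
    source: str = "pubmedkit",
    key: str = "pubmedkit.key",
    date: str | None = None,
) -> tuple[BioCCollection, list[int]]:
    """Export citations as a BioC collection of title/abstract passages.

    One document per PMID with the decimal PMID as document id; the title
    passage sits at offset 0 and the abstract passage (when the citation has
    an abstract) at ``len(title) + 1``.  Returns the collection and the list
    of requested PMIDs that were not found in the store (skipped, not
    fatal).
    """
    if date is None:
        date = _dt.date.today().isoformat()
    documents = []
    skipped = []
    for pmid in pmids:
        citation = store.get(pmid)
        if citation is None:
            skipped.append(pmid)
            continue
        passages = [
            BioCPassage(infons=(("type", "title"),), offset=0, text=citation.title)
        ]
        if citation.abstract is not None:
            passages.append(
                BioCPassage(
                    infons=(("type", "abstract"),),
                    offset=len(citation.title) + len(PASSAGE_SEPARATOR),
                    text=citation.abstract,
                )
            )
        documents.append(BioCDocument(id=str(pmid), passages=tuple(passages)))
    return (
        BioCCollection(source=source, date=date, key=key, documents=tuple(documents)),
        skipped,
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _find_mesh_spans(text: str, descriptors: Sequence[str]) -> list[tuple[int, int]]:
    """Case-insensitive, non-overlapping, leftmost-longest descriptor spans."""
    lowered = text.lower()
    patterns = sorted({d.lower() for d in descriptors if d}, key=len, reverse=True)
    spans: list[tuple[int, int]] = []
    pos = 0
    while pos < len(lowered):
        best: tuple[int, int] | None = None
        for pattern in patterns:  # longest first -> leftmost-longest wins
            found = lowered.find(pattern, pos)
            if found == -1:
                continue
            if best is None or found < best[0]:
                best = (found, found + len(pattern))
        if best is None:
            break
        spans.append(best)
        pos = best[1]
    return spans


def merge_annotations(
    collection: BioCCollection,
    new_annotations: Mapping[str, Sequence[BioCAnnotation]],
    id_suffix: str,
) -> BioCCollection:
    """Merge externally produced annotations into a collection.

    Existing annotations keep their ids.  Added annotations are renumbered
    per document in offset order as ``0_<suffix>``, ``1_<suffix>``, … so
    they remain distinguishable from the plainly numbered ids already
    present.  Each new annotation must satisfy the substring invariant
    against the document text; a violation is rejected naming the
    annotation.
    """
    documents = []
    for document in collection.documents:
        additions = sorted(
            new_annotations.get(document.id, ()), key=lambda a: a.location.offset
        )
        if not additions:
            documents.append(document)
            continue
        text = document.text()
        renumbered = []
        for i, annotation in enumerate(additions):
            start = annotation.location.offset
            end = start + annotation.location.length
            if end > len(text) or text[start:end] != annotation.text:
                raise BioCValidationError(
                    f"document {document.id}: merged annotation {annotation.id!r}"
                    f" text {annotation.text!r} does not match document text at"
                    f" [{start}, {end})"
                )
            renumbered.append(replace(annotation, id=f"{i}_{id_suffix}"))
        # Attach each annotation to the passage containing its offset.
        passages = []
        for passage in document.passages:
            span = range(passage.offset, passage.offset + len(passage.text) + 1)
            mine = tuple(
                a for a in renumbered if a.location.offset in span
            )
            passages.append(
                replace(passage, annotations=passage.annotations + mine)
            )
        documents.append(replace(document, passages=tuple(passages)))
    return replace(collection, documents=tuple(documents))


def annotate_mesh(
    collection: BioCCollection, store: Store
) -> tuple[BioCCollection, list[str]]:
    """Annotate occurrences of each citation's MeSH descriptor names.

    For every document whose id is a PMID known to the store, each
    case-insensitive occurrence of one of that citation's MeSH descriptor
    names in a passage text becomes an annotation (infon ``type=MeSH_term``,
    document-level character offsets, ids ``0_MeSH``, ``1_MeSH``, … in
    offset order).  Matching is non-overlapping and leftmost-longest.
    Documents whose id is not a known PMID are left untouched and reported
    in the second return value.
    """
    new_annotations: dict[str, list[BioCAnnotation]] = {}
    unknown: list[str] = []
    for document in collection.documents:
        try:
            pmid = int(document.id)
        except ValueError:
            pmid = -1
        citation = store.get(pmid) if pmid > 0 else None
        if citation is None:
            unknown.append(document.id)
            continue
        descriptors = [h.descriptor_name for h in citation.mesh_headings]
        if not descriptors:
            continue
        annotations = []
        for passage in document.passages:
            for start, end in _find_mesh_spans(passage.text, descriptors):
                surface = passage.text[start:end]
                annotations.append(
                    BioCAnnotation(
                        id="pending",
                        infons=(("type", "MeSH_term"),),
                        location=BioCLocation(
                            offset=passage.offset + start, length=end - start
                        ),
                        text=surface,
                    )
                )
        if annotations:
            new_annotations[document.id] = annotations
    return merge_annotations(collection, new_annotations, "MeSH"), unknown
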