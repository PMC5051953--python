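"""Stream-parsing of PubMed/MEDLINE citation XML and synthetic corpus generation.

PubMed distributes its bibliographic corpus as XML files in the
``PubmedArticleSet`` dialect (annual baseline plus update files).  This module
turns such files into :class:`Citation` records with a constant-memory
streaming parser, and — because the real corpus needs a network download —
also provides :func:`generate_corpus`, a seeded generator that emits valid
``PubmedArticleSet`` files with a known ground truth, so every downstream
stage (store, index, BioC export, statistics) can be exercised offline.

Only the citation fields the analysis layer touches are modelled: PMID,
title, abstract, journal title abbreviation (``medline_ta``), journal
country, publication year, MeSH headings, keywords, chemical substance
names, and authors.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import IO, Iterator, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Citation",
    "MeshHeading",
    "DeletionMarker",
    "ParseError",
    "parse_citations",
    "generate_corpus",
]


class ParseError(ValueError):
    """Raised for malformed citation XML; carries the reported position."""


@dataclass(frozen=True)
class MeshHeading:
    """One MeSH descriptor attached to a citation.

    ``descriptor_name`` is the controlled-vocabulary term (e.g. "Leukemia"),
    ``qualifiers`` its subheadings, and ``major_topic`` whether the
    descriptor is flagged as a major topic of the article.
    """

    descriptor_name: str
    qualifiers: tuple[str, ...] = ()
    major_topic: bool = False

    def __post_init__(self) -> None:
        if not self.descriptor_name:
            raise ValueError("descriptor_name must be non-empty")


@dataclass(frozen=True)
class Citation:
    """One parsed PubMed citation record."""

    pmid: int
    title: str
    abstract: str | None = None
    journal_ta: str | None = None
    country: str | None = None
    pub_year: int | None = None
    mesh_headings: tuple[MeshHeading, ...] = ()
    keywords: tuple[str, ...] = ()
    chemicals: tuple[str, ...] = ()
    authors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError(f"pmid must be positive, got {self.pmid}")
        if not self.title:
            raise ValueError("title must be non-empty")
        if self.pub_year is not None and not 1000 <= self.pub_year <= 9999:
            raise ValueError(f"pub_year must be a 4-digit year, got {self.pub_year}")


@dataclass(frozen=True)
class DeletionMarker:
    """A PMID listed under ``DeleteCitation`` in an update file."""

    pmid: int


def _text(elem: etree._Element | None) -> str | None:
    if elem is None:
        return None
    value = "".join(elem.itertext()).strip()
    return value or None


def _parse_record(elem: etree._Element) -> Citation | None:
    """Build a Citation from a ``PubmedArticle``/``MedlineCitation`` element."""
    medline = elem if elem.tag == "MedlineCitation" else elem.find("MedlineCitation")
    if medline is None:
        logger.warning("record without MedlineCitation element skipped")
        return None
    pmid_text = _text(medline.find("PMID"))
    if pmid_text is None or not pmid_text.isdigit():
        logger.warning("citation without a usable PMID skipped")
        return None
    pmid = int(pmid_text)

    article = medline.find("Article")
    title = _text(article.find("ArticleTitle")) if article is not None else None
    if title is None:
        logger.warning("citation %d lacks a title; skipped", pmid)
        return None

    # Multi-section abstracts are concatenated with single spaces, labels dropped.
    abstract = None
    if article is not None:
        abstract_elem = article.find("Abstract")
        if abstract_elem is not None:
            sections = [
                s for s in (_text(t) for t in abstract_elem.findall("AbstractText")) if s
            ]
            abstract = " ".join(sections) or None

    journal_info = medline.find("MedlineJournalInfo")
    journal_ta = _text(journal_info.find("MedlineTA")) if journal_info is not None else None
    country = _text(journal_info.find("Country")) if journal_info is not None else None

    pub_year = None
    if article is not None:
        year_text = _text(article.find("Journal/JournalIssue/PubDate/Year"))
        if year_text is None:
            medline_date = _text(article.find("Journal/JournalIssue/PubDate/MedlineDate"))
            if medline_date and medline_date[:4].isdigit():
                year_text = medline_date[:4]
        if year_text and year_text.isdigit():
            pub_year = int(year_text)

    mesh_headings = []
    for heading in medline.findall("MeshHeadingList/MeshHeading"):
        descriptor = heading.find("DescriptorName")
        name = _text(descriptor)
        if name is None:
            continue
        qualifiers = tuple(
            q for q in (_text(e) for e in heading.findall("QualifierName")) if q
        )
        major = descriptor.get("MajorTopicYN", "N") == "Y"
        mesh_headings.append(MeshHeading(name, qualifiers, major))

    keywords = tuple(
        k for k in (_text(e) for e in medline.findall("KeywordList/Keyword")) if k
    )
    chemicals = tuple(
        c
        for c in (
            _text(e) for e in medline.findall("ChemicalList/Chemical/NameOfSubstance")
        )
        if c
    )

    authors = []
    if article is not None:
        for author in article.findall("AuthorList/Author"):
            last = _text(author.find("LastName"))
            initials = _text(author.find("Initials"))
            collective = _text(author.find("CollectiveName"))
            if last:
                authors.append(f"{last} {initials}" if initials else last)
            elif collective:
                authors.append(collective)

    return Citation(
        pmid=pmid,
        title=title,
        abstract=abstract,
        journal_ta=journal_ta,
        country=country,
        pub_year=pub_year,
        mesh_headings=tuple(mesh_headings),
        keywords=keywords,
        chemicals=chemicals,
        authors=tuple(authors),
    )


def parse_citations(source: str | bytes | IO[bytes]) -> Iterator[Citation | DeletionMarker]:
    """Stream-parse citation XML into Citations and DeletionMarkers.

    Parameters
    ----------
    source
        A file path, a bytes buffer, or a binary file object containing a
        ``PubmedArticleSet`` (or ``MedlineCitationSet``) document.

    Yields
    ------
    Citation
        One per citation element, in document order.
    DeletionMarker
        One per PMID listed under a ``DeleteCitation`` element.

    Records missing a PMID or title are skipped with a logged warning.
    Malformed XML raises :class:`ParseError` naming the reported position.
    Parsing is incremental: processed elements are freed as soon as they are
    emitted, so peak memory does not grow with file size.
    """
    if isinstance(source, bytes):
        import io

        source = io.BytesIO(source)
    try:
        context = etree.iterparse(
            source,
            events=("end",),
            tag=("PubmedArticle", "MedlineCitation", "DeleteCitation"),
            resolve_entities=True,
        )
        for _event, elem in context:
            # A MedlineCitation nested inside a PubmedArticle is handled by
            # its parent; only emit for top-level MedlineCitation records.
            if elem.tag == "MedlineCitation" and elem.getparent().tag == "PubmedArticle":
                continue
            if elem.tag == "DeleteCitation":
                for pmid_elem in elem.findall("PMID"):
                    text = _text(pmid_elem)
                    if text and text.isdigit():
                        yield DeletionMarker(int(text))
            else:
                record = _parse_record(elem)
                if record is not None:
                    yield record
            # Free the subtree and any preceding siblings kept by the parser.
            elem.clear()
            while elem.getprevious() is not None:
                del elem.getparent()[0]
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed citation XML: {exc}") from exc


# ---------------------------------------------------------------------------
# Synthetic corpus generation
# ---------------------------------------------------------------------------

#: Controlled vocabulary used for synthetic titles and abstracts.  The terms
#: are drawn from the pancreatic-cancer literature so that generated corpora
#: support realistic phrase and proximity queries.
DEFAULT_VOCAB: tuple[str, ...] = (
    "pancreatic", "cancer", "carcinoma", "adenocarcinoma", "tumour", "gemcitabine",
    "erlotinib", "fluorouracil", "cisplatin", "survival", "patients", "treatment",
    "chemotherapy", "expression", "gene", "mutation", "KRAS", "CDKN2A", "BRCA2",
    "EGFR", "receptor", "kinase", "inhibitor", "metastasis", "prognosis", "therapy",
    "clinical", "trial", "resection", "biomarker", "cells", "growth", "factor",
    "pathway", "signalling", "apoptosis", "proliferation", "diagnosis", "outcome",
    "advanced", "stage", "combined", "randomised", "study", "analysis", "cohort",
    "improves", "response", "tissue", "serum",
)

_JOURNAL_POOL: tuple[tuple[str, str], ...] = (
    ("Cancer Res", "United States"),
    ("Br J Cancer", "England"),
    ("Pancreas", "United States"),
    ("J Clin Oncol", "United States"),
    ("Oncogene", "England"),
    ("Gut", "England"),
    ("Int J Cancer", "Switzerland"),
    ("Lancet", "England"),
    ("Blood", "United States"),
    ("Nature", "England"),
    ("World J Gastroenterol", "China"),
    ("Dtsch Med Wochenschr", "Germany"),
)

_MESH_POOL: tuple[str, ...] = (
    "Leukemia", "Pancreatic Neoplasms", "Carcinoma, Ductal", "Humans", "Mice",
    "Antineoplastic Agents", "Gene Expression", "Mutation", "Survival Analysis",
    "Drug Therapy", "Neoplasm Metastasis", "Biomarkers, Tumor", "Prognosis",
    "Signal Transduction", "Apoptosis", "Cell Proliferation", "Aged",
    "Middle Aged", "Female", "Male",
)

_QUALIFIER_POOL: tuple[str, ...] = (
    "drug therapy", "genetics", "metabolism", "pathology", "surgery", "mortality",
)

_CHEMICAL_POOL: tuple[str, ...] = (
    "Gemcitabine", "Erlotinib Hydrochloride", "Fluorouracil", "Cisplatin",
    "Paclitaxel", "Oxaliplatin", "Capecitabine", "Leucovorin", "Insulin", "Glucose",
)

_KEYWORD_POOL: tuple[str, ...] = (
    "pancreatic cancer", "chemotherapy", "targeted therapy", "biomarker",
    "precision oncology", "tumour microenvironment", "drug resistance",
    "early detection",
)

_SURNAME_POOL: tuple[str, ...] = (
    "Smith", "Mueller", "Tanaka", "Rossi", "Garcia", "Chen", "Kowalski",
    "Johansson", "Dubois", "Okafor", "Novak", "Silva",
)

_YEAR_RANGE = (1990, 2015)
_PMID_BASE = 100001


def _sentence(rng: random.Random, vocab: Sequence[str], n_words: int) -> str:
    words = [rng.choice(vocab) for _ in range(n_words)]
    text = " ".join(words)
    return text[0].upper() + text[1:] + "."


def _make_citation(pmid: int, rng: random.Random, vocab: Sequence[str]) -> Citation:
    title = _sentence(rng, vocab, rng.randint(5, 9))
    abstract = None
    if rng.random() < 0.85:
        abstract = " ".join(
            _sentence(rng, vocab, rng.randint(8, 18)) for _ in range(rng.randint(1, 3))
        )
    journal_ta, country = rng.choice(_JOURNAL_POOL)
    pub_year = rng.randint(*_YEAR_RANGE)
    mesh = tuple(
        MeshHeading(
            name,
            tuple(rng.sample(_QUALIFIER_POOL, rng.randint(0, 2))),
            rng.random() < 0.3,
        )
        for name in rng.sample(_MESH_POOL, rng.randint(0, 5))
    )
    keywords = tuple(rng.sample(_KEYWORD_POOL, rng.randint(0, 3)))
    chemicals = tuple(rng.sample(_CHEMICAL_POOL, rng.randint(0, 3)))
    authors = tuple(
        f"{surname} {''.join(rng.sample('ABCDEFGHJKLMPRST', rng.randint(1, 2)))}"
        for surname in rng.sample(_SURNAME_POOL, rng.randint(1, 4))
    )
    return Citation(
        pmid=pmid,
        title=title,
        abstract=abstract,
        journal_ta=journal_ta,
        country=country,
        pub_year=pub_year,
        mesh_headings=mesh,
        keywords=keywords,
        chemicals=chemicals,
        authors=authors,
    )


def _citation_to_xml(citation: Citation) -> etree._Element:
    article_elem = etree.Element("PubmedArticle")
    medline = etree.SubElement(article_elem, "MedlineCitation")
    etree.SubElement(medline, "PMID").text = str(citation.pmid)
    article = etree.SubElement(medline, "Article")
    journal = etree.SubElement(article, "Journal")
    issue = etree.SubElement(journal, "JournalIssue")
    pubdate = etree.SubElement(issue, "PubDate")
    if citation.pub_year is not None:
        etree.SubElement(pubdate, "Year").text = str(citation.pub_year)
    etree.SubElement(article, "ArticleTitle").text = citation.title
    if citation.abstract is not None:
        abstract = etree.SubElement(article, "Abstract")
        etree.SubElement(abstract, "AbstractText").text = citation.abstract
    if citation.authors:
        author_list = etree.SubElement(article, "AuthorList")
        for name in citation.authors:
            author = etree.SubElement(author_list, "Author")
            parts = name.rsplit(" ", 1)
            etree.SubElement(author, "LastName").text = parts[0]
            if len(parts) == 2:
                etree.SubElement(author, "Initials").text = parts[1]
    journal_info = etree.SubElement(medline, "MedlineJournalInfo")
    if citation.country is not None:
        etree.SubElement(journal_info, "Country").text = citation.country
    if citation.journal_ta is not None:
        etree.SubElement(journal_info, "MedlineTA").text = citation.journal_ta
    if citation.chemicals:
        chem_list = etree.SubElement(medline, "ChemicalList")
        for substance in citation.chemicals:
            chem = etree.SubElement(chem_list, "Chemical")
            etree.SubElement(chem, "NameOfSubstance").text = substance
    if citation.mesh_headings:
        mesh_list = etree.SubElement(medline, "MeshHeadingList")
        for heading in citation.mesh_headings:
            mesh = etree.SubElement(mesh_list, "MeshHeading")
            descriptor = etree.SubElement(mesh, "DescriptorName")
            descriptor.text = heading.descriptor_name
            descriptor.set("MajorTopicYN", "Y" if heading.major_topic else "N")
            for qualifier in heading.qualifiers:
                etree.SubElement(mesh, "QualifierName").text = qualifier
    if citation.keywords:
        kw_list = etree.SubElement(medline, "KeywordList")
        for keyword in citation.keywords:
            etree.SubElement(kw_list, "Keyword").text = keyword
    return article_elem


def generate_corpus(
    n: int, seed: int, vocab: Sequence[str] | None = None
) -> tuple[bytes, list[Citation]]:
    """Generate a synthetic ``PubmedArticleSet`` file with known ground truth.

    Parameters
    ----------
    n
        Number of citation records (PMIDs are sequential from 100001).
    seed
        Seed for the record generator; identical ``(n, seed, vocab)``
        arguments produce byte-identical output.
    vocab
        Optional controlled vocabulary for titles/abstracts; defaults to
        :data:`DEFAULT_VOCAB`.

    Returns
    -------
    (xml_bytes, citations)
        The serialized XML document and the ground-truth Citation list, in
        the same order as the records in the file.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    vocab = tuple(vocab) if vocab is not None else DEFAULT_VOCAB
    rng = random.Random(seed)
    citations = [_make_citation(_PMID_BASE + i, rng, vocab) for i in range(n)]
    root = etree.Element("PubmedArticleSet")
    for citation in citations:
        root.append(_citation_to_xml(citation))
    xml_bytes = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    return xml_bytes, citations
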