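"""BioC interchange: reading, writing, export, annotation, merging."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

import pubmedkit as pk
from pubmedkit.bioc import (
    BioCFormatError,
    BioCValidationError,
    PASSAGE_SEPARATOR,
)


# -- worked example ---------------------------------------------------------


def test_fixture_annotation_zero_is_the_disease_worked_example(bioc_fixture_path):
    """Annotation 0 of document 100475: type Disease, MEDIC id, 77:20 span."""
    collection = pk.read_bioc(bioc_fixture_path)
    assert collection.source and collection.date
    assert collection.key == "PubTator.key"
    (document,) = collection.documents
    assert document.id == "100475"
    annotation = next(a for a in document.annotations() if a.id == "0")
    assert annotation.infon_map["type"] == "Disease"
    assert annotation.infon_map["MEDIC"] == "D010190"
    assert annotation.text == "pancreatic carcinoma"
    assert annotation.location.offset == 77
    assert annotation.location.length == len(annotation.text) == 20
    # the display format of the worked example
    loc = annotation.location
    assert f"{loc.offset}:{loc.length}" == "77:20"


def test_fixture_satisfies_substring_invariant(bioc_fixture_path):
    collection = pk.read_bioc(bioc_fixture_path)
    (document,) = collection.documents
    text = document.text()
    for annotation in document.annotations():
        start = annotation.location.offset
        assert text[start : start + annotation.location.length] == annotation.text


def test_fixture_merged_mesh_ids_follow_suffix_pattern(bioc_fixture_path):
    collection = pk.read_bioc(bioc_fixture_path)
    ids = {a.id for a in collection.documents[0].annotations()}
    assert {"0_MeSH", "1_MeSH"} <= ids


# -- read/write -------------------------------------------------------------


def _collection(documents=(), **kwargs):
    defaults = dict(source="test", date="2016-10-05", key="test.key")
    defaults.update(kwargs)
    return pk.BioCCollection(documents=tuple(documents), **defaults)


def test_empty_collection_round_trips(tmp_path):
    collection = _collection()
    path = pk.write_bioc(collection, tmp_path / "empty.xml")
    assert pk.read_bioc(path) == collection


def test_collection_requires_source_and_date():
    with pytest.raises(ValueError, match="source and date"):
        pk.BioCCollection(source="", date="2016-01-01", key="k")


def test_annotation_length_must_equal_text_length():
    with pytest.raises(ValueError, match="length"):
        pk.BioCAnnotation(
            id="0", infons=(), location=pk.BioCLocation(0, 5), text="abc"
        )


def test_read_rejects_non_bioc_xml(tmp_path):
    path = tmp_path / "bad.xml"
    path.write_text("<notbioc><id>1</id></notbioc>")
    with pytest.raises(BioCFormatError, match="notbioc"):
        pk.read_bioc(path)
    path.write_text("<collection><source>s</source></collection>")
    with pytest.raises(BioCFormatError, match="date"):
        pk.read_bioc(path)


def test_write_refuses_substring_violation(tmp_path):
    passage = pk.BioCPassage(
        infons=(("type", "title"),),
        offset=0,
        text="Short text.",
        annotations=(
            pk.BioCAnnotation(
                id="0", infons=(), location=pk.BioCLocation(0, 5), text="Wrong"
            ),
        ),
    )
    collection = _collection([pk.BioCDocument(id="1", passages=(passage,))])
    with pytest.raises(BioCValidationError, match="annotation 0"):
        pk.write_bioc(collection, tmp_path / "never.xml")
    assert not (tmp_path / "never.xml").exists()


_TEXT = st.text(
    alphabet=st.characters(codec="utf-8", exclude_categories=("Cs", "Cc")),
    min_size=1, max_size=40,
)


@st.composite
def _bioc_collections(draw):
    documents = []
    for d in range(draw(st.integers(0, 3))):
        passages = []
        offset = 0
        for p in range(draw(st.integers(1, 2))):
            text = draw(_TEXT)
            annotations = []
            for a in range(draw(st.integers(0, 2))):
                start = draw(st.integers(0, len(text) - 1))
                end = draw(st.integers(start + 1, len(text)))
                annotations.append(
                    pk.BioCAnnotation(
                        id=f"{a}",
                        infons=(("type", draw(st.sampled_from(["Disease", "Gene"]))),),
                        location=pk.BioCLocation(offset + start, end - start),
                        text=text[start:end],
                    )
                )
            passages.append(
                pk.BioCPassage(
                    infons=(("type", "title" if p == 0 else "abstract"),),
                    offset=offset,
                    text=text,
                    annotations=tuple(annotations),
                )
            )
            offset += len(text) + 1
        documents.append(pk.BioCDocument(id=f"{1000 + d}", passages=tuple(passages)))
    return _collection(documents)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(_bioc_collections())
def test_write_then_read_is_identity_on_random_collections(tmp_path_factory, collection):
    path = tmp_path_factory.mktemp("bioc") / "roundtrip.xml"
    pk.write_bioc(collection, path)
    assert pk.read_bioc(path) == collection


# -- export -----------------------------------------------------------------


def test_export_offsets_and_passage_types(store200, corpus200):
    _, ground_truth = corpus200
    pmids = [c.pmid for c in ground_truth[:30]]
    collection, skipped = pk.export_bioc(store200, pmids)
    assert skipped == []
    by_pmid = {c.pmid: c for c in ground_truth}
    assert [int(d.id) for d in collection.documents] == pmids
    for document in collection.documents:
        citation = by_pmid[int(document.id)]
        title = document.passages[0]
        assert title.infon_map["type"] == "title"
        assert title.offset == 0 and title.text == citation.title
        if citation.abstract is None:
            assert len(document.passages) == 1
        else:
            abstract = document.passages[1]
            assert abstract.infon_map["type"] == "abstract"
            assert abstract.offset == len(citation.title) + len(PASSAGE_SEPARATOR)
            assert abstract.text == citation.abstract


def test_export_reports_unknown_pmids(store200):
    collection, skipped = pk.export_bioc(store200, [100001, 999_999_999])
    assert skipped == [999_999_999]
    assert len(collection.documents) == 1


def test_export_round_trips_through_file(tmp_path, store200):
    collection, _ = pk.export_bioc(store200, store200.pmids()[:10])
    path = pk.write_bioc(collection, tmp_path / "export.xml", key_semantics="sem\n")
    assert pk.read_bioc(path) == collection
    assert (tmp_path / collection.key).read_text() == "sem\n"


# -- MeSH annotation --------------------------------------------------------


def _store_with(pmid, title, abstract, descriptors):
    store = pk.Store()
    store.load([
        pk.Citation(
            pmid=pmid, title=title, abstract=abstract,
            mesh_headings=tuple(pk.MeshHeading(d) for d in descriptors),
        )
    ])
    return store


def test_annotate_mesh_single_occurrence_offsets():
    store = _store_with(1, "Studies of pancreatic carcinoma.", None,
                        ["Pancreatic Carcinoma"])
    collection, _ = pk.export_bioc(store, [1])
    annotated, unknown = pk.annotate_mesh(collection, store)
    assert unknown == []
    (annotation,) = annotated.documents[0].annotations()
    assert annotation.id == "0_MeSH"
    assert annotation.infon_map["type"] == "MeSH_term"
    assert annotation.location.offset == 11
    assert annotation.location.length == 20
    assert annotation.text == "pancreatic carcinoma"  # matched surface, not descriptor


def test_annotate_mesh_two_occurrences_get_distinct_offsets():
    store = _store_with(
        1, "Pancreatic carcinoma update.",
        "New markers of pancreatic carcinoma were found.",
        ["pancreatic carcinoma"],
    )
    collection, _ = pk.export_bioc(store, [1])
    annotated, _ = pk.annotate_mesh(collection, store)
    annotations = annotated.documents[0].annotations()
    assert [a.id for a in annotations] == ["0_MeSH", "1_MeSH"]
    offsets = [a.location.offset for a in annotations]
    assert offsets == sorted(offsets) and len(set(offsets)) == 2
    # annotation in the abstract passage carries a document-level offset
    text = annotated.documents[0].text()
    for a in annotations:
        assert text[a.location.offset : a.location.offset + a.location.length] == a.text


def test_annotate_mesh_descriptor_absent_from_text():
    store = _store_with(1, "Nothing relevant here.", None, ["Leukemia"])
    collection, _ = pk.export_bioc(store, [1])
    annotated, _ = pk.annotate_mesh(collection, store)
    assert annotated.documents[0].annotations() == ()


def test_annotate_mesh_unknown_document_reported_untouched():
    store = _store_with(1, "Known.", None, ["Leukemia"])
    document = pk.BioCDocument(
        id="424242",
        passages=(pk.BioCPassage(infons=(), offset=0, text="Leukemia cells."),),
    )
    collection = _collection([document])
    annotated, unknown = pk.annotate_mesh(collection, store)
    assert unknown == ["424242"]
    assert annotated.documents[0] == document


def test_annotate_mesh_is_leftmost_longest():
    store = _store_with(1, "chronic myeloid leukemia studies.", None,
                        ["Leukemia", "Chronic Myeloid Leukemia"])
    collection, _ = pk.export_bioc(store, [1])
    annotated, _ = pk.annotate_mesh(collection, store)
    (annotation,) = annotated.documents[0].annotations()
    assert annotation.text == "chronic myeloid leukemia"


# -- merging ----------------------------------------------------------------


def _simple_document(existing_ids=("0", "1")):
    text = "Gemcitabine in pancreatic carcinoma therapy."
    annotations = tuple(
        pk.BioCAnnotation(
            id=i, infons=(("type", "Chemical"),),
            location=pk.BioCLocation(0, 11), text="Gemcitabine",
        )
        for i in existing_ids
    )
    passage = pk.BioCPassage(
        infons=(("type", "title"),), offset=0, text=text, annotations=annotations
    )
    return pk.BioCDocument(id="7", passages=(passage,))


def test_merge_suffixes_ids_and_keeps_existing_annotations():
    document = _simple_document()
    new = [
        pk.BioCAnnotation(id="x", infons=(("type", "MeSH_term"),),
                          location=pk.BioCLocation(15, 20),
                          text="pancreatic carcinoma"),
        pk.BioCAnnotation(id="y", infons=(("type", "MeSH_term"),),
                          location=pk.BioCLocation(0, 11), text="Gemcitabine"),
    ]
    merged = pk.merge_annotations(_collection([document]), {"7": new}, "MeSH")
    ids = [a.id for a in merged.documents[0].annotations()]
    assert set(ids) == {"0", "1", "0_MeSH", "1_MeSH"}
    # numbered per document in offset order: Gemcitabine (0) before carcinoma (15)
    by_id = {a.id: a for a in merged.documents[0].annotations()}
    assert by_id["0_MeSH"].text == "Gemcitabine"
    assert by_id["1_MeSH"].text == "pancreatic carcinoma"


def test_merge_zero_annotations_leaves_collection_unchanged():
    collection = _collection([_simple_document()])
    assert pk.merge_annotations(collection, {}, "MeSH") == collection


def test_merge_into_annotation_free_document_starts_at_zero():
    passage = pk.BioCPassage(infons=(), offset=0, text="Plain text body.")
    collection = _collection([pk.BioCDocument(id="9", passages=(passage,))])
    new = [pk.BioCAnnotation(id="n", infons=(), location=pk.BioCLocation(0, 5),
                             text="Plain")]
    merged = pk.merge_annotations(collection, {"9": new}, "MeSH")
    assert [a.id for a in merged.documents[0].annotations()] == ["0_MeSH"]


def test_merge_rejects_substring_violation_naming_annotation():
    collection = _collection([_simple_document()])
    bad = [pk.BioCAnnotation(id="bad", infons=(), location=pk.BioCLocation(0, 5),
                             text="Wrong")]
    with pytest.raises(BioCValidationError, match="'bad'"):
        pk.merge_annotations(collection, {"7": bad}, "MeSH")


def test_merged_collection_round_trips(tmp_path):
    document = _simple_document()
    new = [pk.BioCAnnotation(id="x", infons=(("type", "MeSH_term"),),
                             location=pk.BioCLocation(15, 20),
                             text="pancreatic carcinoma")]
    merged = pk.merge_annotations(_collection([document]), {"7": new}, "MeSH")
    path = pk.write_bioc(merged, tmp_path / "merged.xml")
    assert pk.read_bioc(path) == merged
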