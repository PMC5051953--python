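# pubmedkit

Local PubMed/MEDLINE corpora for text mining: a streaming citation-XML
parser, an embedded relational store, a positional full-text index with
Boolean/phrase/proximity queries, a BioC interchange layer, and the corpus
statistics that literature-mining studies need (entity abstract counts,
publication timelines, ranked journal/author/country aggregates, highlighted
search reports).

## Who this is for

Biomedical text-mining developers who want PubMed citation data — titles,
abstracts, MeSH headings, keywords, chemical substances, authors, journals —
queryable on one machine, with zero services to run, and interoperable with
named-entity-recognition tools through the BioC XML format.  Because the
real corpus requires a bulk download, the package ships a seeded synthetic
corpus generator that emits valid `PubmedArticleSet` XML with a known ground
truth, so every stage of the pipeline can be exercised and verified offline.

## What is inside

* **`pubmed_xml`** — `parse_citations()` stream-parses citation XML with
  constant memory (one `Citation` per record, `DeletionMarker`s for
  `DeleteCitation` entries); `generate_corpus(n, seed)` produces synthetic
  corpora that round-trip exactly.
* **`storage`** — a single-file SQLite store whose table/column names follow
  the classic MEDLINE SQL schema (`tbl_medline_journal_info.medline_ta`,
  `tbl_mesh_heading.descriptor_name`, `fk_pmid`), so the standard
  journals-by-MeSH-descriptor aggregate translates verbatim.  Loading is
  idempotent and partition-order invariant (last occurrence of a PMID wins,
  mirroring PubMed update files).
* **`index`** — a positional inverted index over title, abstract, MeSH
  terms, keywords and chemicals (or a reduced titles+abstracts variant).
  Queries are an AST of `Term`, `And`, `Or`, `AndNot`, `Phrase`, and
  `Near(a, b, k)` — at most *k* intervening words, either order, never
  crossing field boundaries.  Hits are BM25-ranked and scaled so the top
  hit scores exactly 100.  A query mini-language serves the CLI:
  `erlotinib NEAR/4 "pancreatic cancer" AND gemcitabine`.
* **`bioc`** — read/write BioC XML with full fidelity, export store records
  as title/abstract passages (abstract offset = title length + 1), annotate
  case-insensitive occurrences of each record's MeSH descriptor names with
  exact character offsets, and merge externally produced annotations under
  suffixed ids (`0_MeSH`, `1_MeSH`, …).  Every produced annotation is
  validated against the substring invariant before writing.
* **`analytics`** — entity abstract counts from NER mention TSVs (distinct
  PMIDs per identifier, synonyms summarised), word-cloud weights (top 150,
  max weight 1.0), identifier-group merging, publication-year timelines,
  whitespace-tokeniser term frequencies, and an HTML search report with
  `<mark>`-highlighted terms.

## Worked example

```bash
pubmedkit synth --n 200 --seed 11 --out corpus.xml
pubmedkit load corpus.xml --store corpus.db
pubmedkit index --store corpus.db --mode full
pubmedkit search '"pancreatic cancer" AND gemcitabine' --store corpus.db --limit 5
pubmedkit stats journals --store corpus.db --descriptor "Pancreatic Neoplasms" --limit 5
```

prints (rank, relevance score, PMID, title; then journal, publication count):

```
1	100.0	100094	Gemcitabine carcinoma signalling cancer chemotherapy.
2	89.4	100118	Gemcitabine trial gemcitabine erlotinib pancreatic fluorouracil receptor stage.
3	89.2	100150	Prognosis EGFR randomised serum therapy inhibitor gemcitabine therapy.
4	85.5	100146	Metastasis EGFR outcome cells diagnosis clinical.
5	85.3	100076	Study biomarker erlotinib apoptosis cisplatin.

Oncogene	6
Blood	4
Br J Cancer	4
Gut	4
Pancreas	4
```

The search lists every record whose indexed fields contain the consecutive
phrase "pancreatic cancer" *and* the token "gemcitabine" anywhere; the score
column is the BM25 weight of the matched terms rescaled so the best hit is
100.  The journal table counts distinct records per journal carrying the
MeSH descriptor `Pancreatic Neoplasms`, ranked descending.  The same
operations are available as library functions (`pubmedkit.search`,
`Store.journals_by_descriptor`, …); `--html results.html` on `search`
writes the highlighted HTML report.

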