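# Methods

This note documents the models, conventions, and numerical choices behind
pubmedkit, what the synthetic corpus generator does and does not emulate,
and the known limitations.

## Citation model and parsing

A `Citation` models the subset of a MEDLINE record that the query and
statistics layers touch: PMID, title, optional abstract, journal title
abbreviation (`medline_ta`), journal country, publication year, MeSH
headings (descriptor, qualifiers, major-topic flag), keywords, chemical
substance names, and authors (surname + initials).  The full MEDLINE DTD
carries far more (grants, history dates, investigator lists); those fields
are deliberately out of scope.

Parsing is incremental (`lxml.etree.iterparse`): each record element is
converted and freed immediately, so memory is bounded independently of file
size.  Conventions:

* **Multi-section abstracts** (labelled `AbstractText` elements) are
  concatenated with single spaces; labels are discarded.  The store keeps
  one abstract text per record.
* **Publication year** comes from `PubDate/Year`, falling back to the first
  four digits of `MedlineDate` when only that is present.
* **Duplicate PMIDs** within and across batches: the last occurrence wins.
  PubMed distributes annual baselines plus update files in which later
  records supersede earlier ones; last-wins reproduces the state after
  applying updates in order.  `DeleteCitation` entries become deletion
  markers that remove the PMID from the store.
* Records missing a PMID or title are skipped with a logged warning rather
  than aborting the batch; malformed XML aborts with a parse error naming
  the position.
* Encoding is UTF-8 throughout; XML entities are resolved by the parser.

## Relational store

SQLite, one file per store, schema names following the classic MEDLINE SQL
loaders (`tbl_medline_citation`, `tbl_medline_journal_info.medline_ta`,
`tbl_mesh_heading.descriptor_name`, `fk_pmid`) so that the standard
journals-by-descriptor SQL translates verbatim.  Child tables reference the
citation row with `ON DELETE CASCADE`, so referential integrity survives
any load/delete sequence.

Ranked aggregates (`journals_by_descriptor`, `group_count`) count **distinct
PMIDs** per group value and break ties lexicographically ascending on the
grouped value — the tie rule is this package's fixed choice, made so that
results are reproducible across runs and load orders.  Descriptor matching
is exact and case-sensitive, as SQL equality would be.

State comparison uses a canonical logical dump (`Store.state_dump()`): all
tables serialized with rows sorted by content and surrogate keys normalised
away.  Two stores hold the same data iff their dumps are byte-identical;
raw SQLite file bytes are not comparable because page layout depends on
insertion history.

## Tokenisation and the positional index

The tokenizer splits on whitespace, strips leading/trailing punctuation
(ASCII punctuation plus common typographic quotes/dashes), lowercases, and
drops empty results; internal punctuation is kept (`CA19-9` → `ca19-9`).
There is no stemming and no stopword list — queries mean what they say.

The index maps term → {(PMID, field instance) → sorted positions}.  Each
field instance — the title, the abstract, each MeSH descriptor, each
keyword, each chemical name — is an independent position space, so phrase
and proximity matches never cross field boundaries.  Two field sets exist:
`full` (title, abstract, MeSH, keywords, chemicals) and
`titles_abstracts_only`.  The index is rebuilt rather than incrementally
updated, and persists as JSON beside the store file.

### Query semantics

* `And`/`Or`/`AndNot`: set intersection/union/difference on hit sets.
* `Phrase`: strictly consecutive positions within a single field instance.
* `Near(a, b, k)`: both operands occur in the same field instance with
  `|pos(a) − pos(b)| ≤ k + 1`, in either order — i.e. at most `k`
  intervening words.  "Up to four other words between the terms, without
  fixed word order" is exactly `Near(..., k=4)`.  Operands are terms or
  phrases; a phrase's position is its first token's position (the simplest
  consistent convention; the alternative — nearest-edge distance — would
  only relax matches by the phrase length).
* A query string language provides the same operators for the CLI, with
  precedence OR < AND/NOT < NEAR/k and quoted phrases.  The window `k` is
  mandatory in `NEAR/k`; a bare `NEAR` is rejected rather than given an
  implicit default.

### Ranking

Scores are BM25 (k1 = 1.2, b = 0.75, document length = total indexed
tokens, idf = ln(1 + (N − df + 0.5)/(df + 0.5)), which is strictly
positive) summed over the query's *positive* terms — terms under the
excluded branch of `AndNot` contribute nothing.  Scores are then scaled so
the best hit is exactly 100 and others proportional in (0, 100]; ties break
by PMID ascending.  The hit *set* is purely Boolean/positional; BM25 only
orders it, so any monotone ranking would produce the same sets.  The scale
division is performed as `(s/top)·100` with a clamp at 100 so ties at the
maximum cannot exceed 100 by a rounding ulp.

## BioC interchange

Offsets are 0-based **character** (not byte) offsets into the document
text, half-open `[offset, offset + length)`.  The document text is the
concatenation of passage texts with a one-character separator; hence an
exported abstract passage starts at `len(title) + 1`.  One space is the
common convention for BioC renderings of PubMed records; nothing downstream
depends on the separator being a space, only on its width being one.

Every writer validates the substring invariant — the document text at an
annotation's location must equal its `text` — before emitting XML, and
`read(write(c)) == c` on the in-memory model.  Written files carry a
`BioC.dtd` doctype and a companion `.key` file describing the semantics of
the infons used, which is how BioC separates structure from meaning.

MeSH annotation matches each record's descriptor names in its passages
case-insensitively, non-overlapping, leftmost-longest, with no stemming —
the simplest well-defined string-matching rule.  Merged annotations are
renumbered `0_<suffix>`, `1_<suffix>`, … per document in offset order, so
they remain distinguishable from the plainly numbered ids produced by NER
services; existing annotations are never touched.  Mixed annotation types
in one file are permitted (provenance lives in the infons), although
single-type files remain the cleaner interchange practice.

## Entity statistics

An entity's "abstract count" is the number of **distinct PMIDs** in which
any synonym of its identifier was found — mention multiplicity within one
abstract does not matter.  Mentions whose identifier is empty (entity
normalisation can fail) fall back to grouping by surface form.  The
representative synonym of an identifier is its most frequent surface form,
ties lexicographic.  `merge_identifiers` unions the PMID sets of a group
(e.g. organism-specific Entrez GeneIDs of one gene) before counting, so a
merged count is the union size, never the sum.  Word-cloud weights are
counts scaled to max = 1.0; the default table size of 150 matches common
word-cloud practice.  Timelines zero-fill years inside the observed range
and report PMIDs lacking a stored year separately.  Highlighting in the
HTML report is case-insensitive, non-overlapping, leftmost-first, longer
terms winning ties at the same position.

## Synthetic corpus generator

`generate_corpus(n, seed)` emits a valid `PubmedArticleSet` with sequential
PMIDs from 100001 and, per record: a title of 5–9 words and (85% of
records) an abstract of 1–3 sentences drawn from a ~50-term oncology
vocabulary; a journal (with country) from a 12-journal pool; a publication
year uniform in 1990–2015; 0–5 MeSH headings from a 20-descriptor pool
(with 0–2 qualifiers and a 30% major-topic rate); 0–3 keywords; 0–3
chemical names; 1–4 authors.  Output is byte-deterministic in
`(n, seed, vocab)`.

The generator emulates the *structure* of PubMed XML — everything the
parser, store, index, and BioC layers consume — with enough lexical overlap
that phrase and proximity queries have non-trivial hit sets.  It does not
emulate natural language (word order is random), the long-tailed journal
and MeSH distributions of real PubMed, multi-section abstracts, or
non-ASCII text.  Passing tests therefore demonstrate the correctness of
parsing, storage, query evaluation, interchange, and counting — not
retrieval quality on real prose, which depends on none of those contracts.

Test and verification problem sizes — 200–300-record corpora, 100 random
queries per operator class, 50 randomized BioC collections, ~1200-row
mention files — were chosen as the smallest sizes at which every code path
and tie-break is exercised many times over.

## Known limitations

* Single-writer embedded store; no concurrent service mode.
* No wildcards, fuzzy matching, stemming, or incremental index updates.
* Only the modelled citation fields are stored; the full MEDLINE DTD is not.
* Gene/disease/chemical recognition itself is out of scope: the analytics
  layer consumes mention TSVs produced by external NER tools.
* The index is held in memory while building; corpora far beyond the
  synthetic scale would need a disk-backed posting store.
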