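Synthetic key file for the stand-in collection bioc_synthetic_100475.xml.

collection: PubMed citations exported as title/abstract passages.
document id: the PubMed ID of the citation.
passage infon "type": title | abstract.
annotation infon "type": Disease (normalised mention; infon "MEDIC" holds the
  MeSH/OMIM disease id) or MeSH_term (MeSH descriptor occurrence located in
  the passage text).
annotation location: 0-based character offset into the concatenated document
  text and character length of the annotated span.
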