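<?xml version='1.0' encoding='UTF-8'?>
<!DOCTYPE collection SYSTEM "BioC.dtd">
<!-- Synthetic stand-in document for PMID 100475: the annotation ids, types,
     MEDIC id, and the 77:20 location of annotation 0 are the reference
     values this suite checks against, but the title and abstract text are
     invented; they were engineered so that every annotation satisfies the
     substring invariant at those offsets. -->
<collection>
  <source>PubTator</source>
  <date>2016-10-05</date>
  <key>PubTator.key</key>
  <document>
    <id>100475</id>
    <passage>
      <infon key="type">title</infon>
      <offset>0</offset>
      <text>Expression profiles of mucin genes in human pancreatic tumour specimens.</text>
    </passage>
    <passage>
      <infon key="type">abstract</infon>
      <offset>73</offset>
      <text>The pancreatic carcinoma specimens were compared with healthy tissue, and markers of pancreatic carcinoma were scored.</text>
      <annotation id="0">
        <infon key="type">Disease</infon>
        <infon key="MEDIC">D010190</infon>
        <location offset="77" length="20"/>
        <text>pancreatic carcinoma</text>
      </annotation>
      <annotation id="0_MeSH">
        <infon key="type">MeSH_term</infon>
        <location offset="77" length="20"/>
        <text>pancreatic carcinoma</text>
      </annotation>
      <annotation id="1_MeSH">
        <infon key="type">MeSH_term</infon>
        <location offset="158" length="20"/>
        <text>pancreatic carcinoma</text>
      </annotation>
    </passage>
  </document>
</collection>
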