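<?xml version='1.0' encoding='UTF-8'?>
<SAMPLE_SET>
  <SAMPLE accession="ERS000002">
    <IDENTIFIERS>
      <PRIMARY_ID>ERS000002</PRIMARY_ID>
      <EXTERNAL_ID namespace="BioSample">SAMEA0000002</EXTERNAL_ID>
    </IDENTIFIERS>
    <DESCRIPTION>Survey vent estuary profiling hydrothermal survey microbial diversity gradient archaeal.</DESCRIPTION>
    <SAMPLE_ATTRIBUTES>
      <SAMPLE_ATTRIBUTE>
        <TAG>depth</TAG>
        <VALUE>transect sulfate</VALUE>
        <UNITS>m</UNITS>
      </SAMPLE_ATTRIBUTE>
      <SAMPLE_ATTRIBUTE>
        <TAG>collection date</TAG>
        <VALUE>community archaeal</VALUE>
      </SAMPLE_ATTRIBUTE>
    </SAMPLE_ATTRIBUTES>
  </SAMPLE>
</SAMPLE_SET>
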