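<?xml version='1.0' encoding='UTF-8'?>
<SAMPLE_SET>
  <SAMPLE accession="ERS000003">
    <IDENTIFIERS>
      <PRIMARY_ID>ERS000003</PRIMARY_ID>
      <EXTERNAL_ID namespace="BioSample">SAMEA0000003</EXTERNAL_ID>
    </IDENTIFIERS>
    <DESCRIPTION>Hydrothermal benthic coastal carbon reducing cycling sediment shotgun microbial hydrothermal.</DESCRIPTION>
    <SAMPLE_ATTRIBUTES>
      <SAMPLE_ATTRIBUTE>
        <TAG>environment (biome)</TAG>
        <VALUE>vent bloom</VALUE>
      </SAMPLE_ATTRIBUTE>
      <SAMPLE_ATTRIBUTE>
        <TAG>depth</TAG>
        <VALUE>benthic profiling</VALUE>
        <UNITS>m</UNITS>
      </SAMPLE_ATTRIBUTE>
      <SAMPLE_ATTRIBUTE>
        <TAG>temperature</TAG>
        <VALUE>diversity vent</VALUE>
        <UNITS>DegreeCelsius</UNITS>
      </SAMPLE_ATTRIBUTE>
    </SAMPLE_ATTRIBUTES>
  </SAMPLE>
</SAMPLE_SET>
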