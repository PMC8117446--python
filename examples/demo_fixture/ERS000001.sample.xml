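<?xml version='1.0' encoding='UTF-8'?>
<SAMPLE_SET>
  <SAMPLE accession="ERS000001">
    <IDENTIFIERS>
      <PRIMARY_ID>ERS000001</PRIMARY_ID>
      <EXTERNAL_ID namespace="BioSample">SAMEA0000001</EXTERNAL_ID>
    </IDENTIFIERS>
    <DESCRIPTION>Diversity amplicon metagenome pelagic community bacterial profiling microbial diversity sediment.</DESCRIPTION>
    <SAMPLE_ATTRIBUTES>
      <SAMPLE_ATTRIBUTE>
        <TAG>geographic location (country and/or sea)</TAG>
        <VALUE>reducing shotgun</VALUE>
      </SAMPLE_ATTRIBUTE>
      <SAMPLE_ATTRIBUTE>
        <TAG>environment (biome)</TAG>
        <VALUE>cycling hydrothermal</VALUE>
      </SAMPLE_ATTRIBUTE>
      <SAMPLE_ATTRIBUTE>
        <TAG>depth</TAG>
        <VALUE>sulfate diversity</VALUE>
        <UNITS>m</UNITS>
      </SAMPLE_ATTRIBUTE>
    </SAMPLE_ATTRIBUTES>
  </SAMPLE>
</SAMPLE_SET>
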