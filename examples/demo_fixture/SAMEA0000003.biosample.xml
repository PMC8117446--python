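<?xml version='1.0' encoding='UTF-8'?>
<BioSample accession="SAMEA0000003">
  <Property class="depth">
    <QualifiedValue>
      <Value>nitrogen nitrogen</Value>
      <Unit>m</Unit>
    </QualifiedValue>
  </Property>
  <Property class="salinity">
    <QualifiedValue>
      <Value>microbial estuary</Value>
      <Unit>psu</Unit>
    </QualifiedValue>
  </Property>
  <Property class="elevation">
    <QualifiedValue>
      <Value>bloom coastal</Value>
      <Unit>m</Unit>
    </QualifiedValue>
  </Property>
  <Property class="elevation">
    <QualifiedValue>
      <Value>profiling cycling</Value>
      <Unit>m</Unit>
    </QualifiedValue>
  </Property>
</BioSample>
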