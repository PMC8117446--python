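<?xml version='1.0' encoding='UTF-8'?>
<BioSample accession="SAMEA0000002">
  <Property class="environment (material)">
    <QualifiedValue>
      <Value>marine sulfate</Value>
    </QualifiedValue>
  </Property>
  <Property class="environment (material)">
    <QualifiedValue>
      <Value>estuary assembly</Value>
    </QualifiedValue>
  </Property>
  <Property class="collection date">
    <QualifiedValue>
      <Value>reducing sediment</Value>
    </QualifiedValue>
  </Property>
  <Property class="depth">
    <QualifiedValue>
      <Value>hydrothermal gradient</Value>
      <Unit>m</Unit>
    </QualifiedValue>
  </Property>
</BioSample>
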