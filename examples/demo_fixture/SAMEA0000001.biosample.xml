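<?xml version='1.0' encoding='UTF-8'?>
<BioSample accession="SAMEA0000001">
  <Property class="elevation">
    <QualifiedValue>
      <Value>reducing profiling</Value>
      <Unit>m</Unit>
    </QualifiedValue>
  </Property>
  <Property class="Organism">
    <QualifiedValue>
      <Value>transect profiling</Value>
    </QualifiedValue>
  </Property>
  <Property class="elevation">
    <QualifiedValue>
      <Value>amplicon diversity</Value>
      <Unit>m</Unit>
    </QualifiedValue>
  </Property>
  <Property class="salinity">
    <QualifiedValue>
      <Value>gradient profiling</Value>
      <Unit>psu</Unit>
    </QualifiedValue>
  </Property>
</BioSample>
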