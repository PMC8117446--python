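<?xml version='1.0' encoding='UTF-8'?>
<EXPERIMENT_SET>
  <EXPERIMENT accession="ERX000002">
    <DESIGN>
      <DESIGN_DESCRIPTION>Diversity gradient bacterial polar shotgun estuary community diversity.</DESIGN_DESCRIPTION>
      <LIBRARY_DESCRIPTOR>
        <LIBRARY_STRATEGY>AMPLICON</LIBRARY_STRATEGY>
      </LIBRARY_DESCRIPTOR>
    </DESIGN>
    <PLATFORM>
      <ILLUMINA>
        <INSTRUMENT_MODEL>Illumina HiSeq 2500</INSTRUMENT_MODEL>
      </ILLUMINA>
    </PLATFORM>
  </EXPERIMENT>
</EXPERIMENT_SET>
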