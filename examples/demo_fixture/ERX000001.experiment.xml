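<?xml version='1.0' encoding='UTF-8'?>
<EXPERIMENT_SET>
  <EXPERIMENT accession="ERX000001">
    <DESIGN>
      <DESIGN_DESCRIPTION>Sediment survey sediment bacterial fjord coastal gradient cycling.</DESIGN_DESCRIPTION>
      <LIBRARY_DESCRIPTOR>
        <LIBRARY_STRATEGY>WGS</LIBRARY_STRATEGY>
      </LIBRARY_DESCRIPTOR>
    </DESIGN>
    <PLATFORM>
      <PACBIO_SMRT>
        <INSTRUMENT_MODEL>Sequel II</INSTRUMENT_MODEL>
      </PACBIO_SMRT>
    </PLATFORM>
  </EXPERIMENT>
</EXPERIMENT_SET>
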