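<?xml version='1.0' encoding='UTF-8'?>
<experiments>
  <experiment>
    <accession>E-MTAB-1</accession>
    <name>Benthic coastal nitrogen amplicon sediment microbial</name>
  </experiment>
</experiments>
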