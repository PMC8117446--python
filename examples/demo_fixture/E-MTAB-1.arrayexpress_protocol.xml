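<?xml version='1.0' encoding='UTF-8'?>
<protocols>
  <protocol>
    <type>nucleic acid extraction protocol</type>
    <text>Shotgun bloom nitrogen survey coastal microbial estuary coastal survey shotgun survey marine.</text>
    <hardware>QIAGEN DNeasy PowerSoil</hardware>
  </protocol>
  <protocol>
    <type>nucleic acid library construction protocol</type>
    <text>Diversity estuary seasonal gradient marine coastal cycling bacterial pelagic assembly diversity benthic.</text>
    <hardware>Illumina HiSeq 2500</hardware>
    <software>bcl2fastq 2.20</software>
  </protocol>
</protocols>
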