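<?xml version='1.0' encoding='UTF-8'?>
<STUDY_SET>
  <STUDY accession="ERP000001">
    <IDENTIFIERS>
      <PRIMARY_ID>ERP000001</PRIMARY_ID>
    </IDENTIFIERS>
    <DESCRIPTOR>
      <STUDY_TITLE>Benthic coastal nitrogen amplicon sediment microbial</STUDY_TITLE>
    </DESCRIPTOR>
    <abstract>Polar bacterial community pelagic diversity sediment carbon archaeal metagenome sediment microbial cycling cycling microbial survey microbial bacterial cycling sediment polar diversity community survey amplicon amplicon.</abstract>
    <STUDY_LINKS>
      <STUDY_LINK>
        <XREF_LINK>
          <DB>ENA-FASTQ-FILES</DB>
          <ID>ftp.sra.ebi.ac.uk/vol1/fastq/ERP000001</ID>
        </XREF_LINK>
      </STUDY_LINK>
      <STUDY_LINK>
        <XREF_LINK>
          <DB>ENA-EXPERIMENT</DB>
          <ID>ERX000001-ERX000002</ID>
        </XREF_LINK>
      </STUDY_LINK>
      <STUDY_LINK>
        <XREF_LINK>
          <DB>ENA-SAMPLE</DB>
          <ID>ERS000001-ERS000003</ID>
        </XREF_LINK>
      </STUDY_LINK>
      <STUDY_LINK>
        <XREF_LINK>
          <DB>ARRAYEXPRESS</DB>
          <ID>E-MTAB-1</ID>
        </XREF_LINK>
      </STUDY_LINK>
    </STUDY_LINKS>
  </STUDY>
</STUDY_SET>
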