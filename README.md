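# omicspaper

Convert the linked XML metadata of a European Nucleotide Archive (ENA)
study into a structured **omics data paper** manuscript.

## The problem

Sequencing studies deposited in ENA carry rich, standard-compliant
metadata — study abstracts, experiment library descriptors and platforms,
sample attributes, MIxS checklists in BioSamples, MINSEQE-curated
protocols in ArrayExpress — but that metadata rarely reaches a
human-readable, citable narrative. A *data paper* is a peer-reviewed
article whose primary content is the description of a dataset; writing one
by hand means re-typing metadata that already exists in machine-readable
form.

`omicspaper` automates the conversion. Starting from a single Study or
Project accession (`ERP*`/`SRP*`/`DRP*` or `PRJEB*`/`PRJNA*`/`PRJDB*`) it:

1. fetches the study/project XML, whose `XREF_LINK` blocks name every
   linked experiment and sample (often as hyphenated accession ranges such
   as `ERX000001-ERX000002`), plus optional ArrayExpress and FASTQ links;
2. fetches and parses each linked document with the template's XPath
   expressions (`//abstract`,
   `//EXPERIMENT/DESIGN/LIBRARY_DESCRIPTOR/LIBRARY_STRATEGY`,
   `//EXPERIMENT/PLATFORM`, `//SAMPLE/DESCRIPTION`,
   `//SAMPLE/SAMPLE_ATTRIBUTES/SAMPLE_ATTRIBUTE`,
   `//XREF_LINK/ID[../DB = 'ENA-FASTQ-FILES']`,
   `//SAMPLE/IDENTIFIERS/EXTERNAL_ID[@namespace = 'BioSample']`,
   `//Property[@class]`, and the ArrayExpress
   `protocol/type|text|hardware|software` fields), kept in one auditable
   registry (`omicspaper.parsers.XPATH_REGISTRY`);
3. assembles the fixed data-paper section template, auto-filling the
   sections the metadata can support — Abstract, Methods/Sampling,
   Methods/Sample processing/Technologies used, Data resources, and the
   Supplementary material — and emitting every other section as a guidance
   placeholder marked `[TO BE COMPLETED BY AUTHORS]`;
4. pivots the BioSamples MIxS properties into a narrow-format table (one
   row per biosample × property) and renders the manuscript as JATS XML
   (each section a `<sec sec-type="...">` element, e.g.
   `<sec sec-type="Methods">`), standalone HTML, and the checklist CSV.

Methods and Data resources are mandatory: `validate()` flags a manuscript
in which either is empty or placeholder-only. The supplementary checklist
cannot be edited or removed through the API; the only way to change it is
`reimport_biosamples()`, which refetches the records from the source and
re-pivots the table, leaving every other section untouched.

Everything runs offline against a fixture directory, and the package ships
a synthetic-bundle generator (`omicspaper.fixtures`) that produces an
internally cross-referenced document set together with the ground-truth
records it encodes — the basis of the test suite.

## Worked example

A demo fixture set (1 study, 2 experiments, 3 samples, 3 BioSamples, 1
ArrayExpress experiment with protocols) is checked in under
`examples/demo_fixture/`:

```sh
omicspaper ERP000001 --fixtures examples/demo_fixture --out demo_out
```

prints

```
ERP000001: wrote 3 files to demo_out (5 auto-filled sections, 0 warnings)
```

meaning: the study document was fetched, its cross-references resolved to
2 experiments and 3 samples (doc counts in `demo_out/run_report.json`:
`{"study": 1, "experiment": 2, "sample": 3, "biosample": 3,
"arrayexpress_protocol": 1}`), and the five auto-fillable template
sections were populated from metadata. The three outputs are
`ERP000001.html` (the manuscript narrative), `ERP000001.jats.xml` (the
JATS article), and `ERP000001.mixs_checklist.csv`, whose first lines are:

```
biosample_accession,property_class,value,unit
SAMEA0000001,elevation,reducing profiling,m
SAMEA0000001,Organism,transect profiling,
SAMEA0000001,elevation,amplicon diversity,m
SAMEA0000001,salinity,gradient profiling,psu
```

— one row per MIxS property per biosample (12 rows for 3 biosamples × 4
properties; values here are seeded synthetic text). Running the same
command twice produces byte-identical files.

For a live run, omit `--fixtures`; endpoint URLs, timeout, and retries can
be overridden with `--config FILE` (`key=value` lines, see
`omicspaper.transport.EndpointConfig`). Exit codes: 0 success, 3 invalid
accession, 4 study record missing, 5 network failure; failures on linked
documents downgrade to warnings in `run_report.json`.

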