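# Methods

## Conversion model

The package treats an omics data paper as a deterministic function of the
metadata graph rooted at one ENA study or project accession. The graph is
traversed in a fixed order: study/project document → cross-references
(`XREF_LINK` blocks) → experiment and sample documents → BioSamples
records (via each sample's `EXTERNAL_ID` in the `BioSample` namespace) →
ArrayExpress protocols (via an `E-XXXX-n` identifier among the
cross-references). Each document contributes to the manuscript only
through the XPath expressions in `parsers.XPATH_REGISTRY`; nothing is
inferred or fabricated, and a missing source leaves its target section
explicitly empty with a logged miss. This makes the output reproducible:
for a fixed document set the rendered JATS, HTML, and CSV are byte-stable.

### Accession grammar

ENA prints no formal grammar for its identifiers, so the package adopts
the public INSDC prefix conventions: `ERP|SRP|DRP` (study),
`PRJEB|PRJNA|PRJDB` (project), `ERX|SRX|DRX` (experiment), `ERS|SRS|DRS`
(sample), `SAMEA|SAMN|SAMD` (BioSamples), `ERR|SRR|DRR` (run),
`E-[A-Z]{4}-n` (ArrayExpress). `SAM*` identifiers deliberately classify as
*biosample*, not *sample*, so they route to the BioSamples arm rather than
the ENA sample endpoint. Classification is total (anything else is
`unknown`); range expansion preserves the start token's zero padding and
caps at 10,000 items as a guard against malformed link text — beyond that
a range is more plausibly a corrupted cross-reference than a real object
list. Hyphenated ArrayExpress ranges are parsed by trying every hyphen as
the separator, since the identifiers contain hyphens themselves.
Run-level accessions classify but are never fetched; run and analysis
objects are outside the manuscript template's source fields.

### XPath evaluation

Expressions are evaluated namespace-agnostically: the document tree is
parsed with lxml and element/attribute namespaces are stripped before
evaluation, because ENA dialects vary in default-namespace usage while the
template's expressions are written without prefixes. Element matches
yield their XPath string-value (concatenated descendant text), attribute
matches the attribute value, always in document order. When a
single-valued field matches multiple nodes (e.g. two abstracts), the first
match wins and a warning is logged — deterministic output over guessing.
`//EXPERIMENT/PLATFORM` matches a container element; the record keeps the
platform family (the tag of the container's single child, e.g.
`ILLUMINA`) and the `INSTRUMENT_MODEL` text beneath it, rendered as
`"FAMILY MODEL"`. Each `SAMPLE_ATTRIBUTE` block decomposes into the
standard SRA (TAG, VALUE, UNITS) triple. A BioSamples `Property[@class]`
yields one table row per nested `Value` element, with the unit taken from
the `Unit` element beside that value when present.

## The manuscript template

The section tree is fixed: Abstract; Introduction (Value of the dataset:
Scientific value, Societal value); Methods (Sampling: Environmental
profile, Geographic range, Technologies used; Sample processing:
Technologies used; Data processing); Biodiversity profile (Target,
Taxonomic range, Functional range, Traits); Data resources; Data
statistics; Caveats and limitations; Usage rights; Supplementary
material. Exactly five sections are auto-fillable — Abstract,
Methods/Sampling, Methods/Sample processing/Technologies used, Data
resources, Supplementary material — and exactly two are mandatory:
Methods and Data resources.

Design choices where the template was genuinely open:

- **Placeholders** carry the section's guidance text plus the literal
  marker `[TO BE COMPLETED BY AUTHORS]`, so validation is mechanical: a
  mandatory section violates iff its subtree holds no non-empty
  auto-populated block.
- **Sampling** groups content per sample, ordered by sample accession;
  the template is silent on ordering and accession order is stable.
- **Data resources** renders the FASTQ link first, then experiment
  accessions, then sample accessions, as labeled lists.
- **Deduplication** of repeated library-strategy/platform strings is
  case-sensitive exact match, to avoid silently merging distinct
  instruments.
- **Section ids** equal the display titles and double as the JATS
  `sec-type` values (`<sec sec-type="Methods">`). Two sections share the
  title "Technologies used"; they are addressed by path internally, and
  the duplicate `sec-type` is legal JATS.

### Supplementary checklist and re-import

BioSamples MIxS properties pivot into a narrow (long-format) table — one
row per (biosample, property) pair, grouped by biosample in input order,
duplicates retained. The CSV dialect is pinned for reproducibility:
comma delimiter, double-quote quoting with quote doubling, UTF-8, LF line
endings, header `biosample_accession,property_class,value,unit` (the unit
column is present even when all units are absent, for a stable schema).

The attached table is immutable through the manuscript API; the sole
mutation path is `reimport_biosamples`, which refetches every recorded
biosample and re-pivots. With unchanged sources the operation is
idempotent (byte-identical rendering). A biosample that has gone missing
upstream is reported as a warning and its stale rows are retained
per-accession, so a transient upstream gap never silently truncates the
published checklist.

## Transport

One fetch contract, two backends. The live backend uses configurable URL
templates (defaults point at the public ENA browser, BioSamples, and
ArrayExpress XML retrieval patterns), with `retry_count` attempts, an
HTTP 404/410 mapped to *missing-record* without retry, and everything
else exhausting retries into *network-failure*; payloads that do not
parse as XML are *malformed-payload*. The taxonomy is closed — every
failure is exactly one of the three. The live backend caches fetched
documents per run; the fixture backend deliberately does not, reading
disk on every call so that re-import observes fixture edits, which is the
point of the re-import semantics. The fixture directory layout is one
file per document, `"<accession>.<doc_kind>.xml"`, self-describing and
byte-deterministic.

## Synthetic bundles

`fixtures.generate` emulates the linked document set of a small
sequencing study and returns the ground-truth records alongside the
documents, enabling exact round-trip testing offline. Default study
conditions (also the checked-in demo): 1 study, 2 experiments, 3 samples,
BioSamples links on every sample with 4 MIxS properties each, an
ArrayExpress experiment with 2 protocols, and no missing fields — a
deliberately small but fully linked graph exercising every branch of the
traversal. Accessions are allocated sequentially per kind (`ERP000001`,
`ERX000001`, …) independent of seed; the seed drives text content drawn
from a fixed vocabulary, so diffs stay readable and bundles are
byte-reproducible. Experiment/sample cross-references are written as
hyphenated ranges whenever the count is ≥ 2, exercising range expansion
on the default path.

`missing_field_rate` (default 0) drops only fields that are conditionally
present in real records — the FASTQ cross-reference, per-sample BioSample
links, attribute/property units, protocol hardware/software — each with
independent probability; at rate 1.0 every such field is absent from both
documents and truth, covering every empty-case contract.

What the generator does **not** emulate, and what passing tests therefore
do not show about real data: schema-version drift across ENA releases,
default-namespace documents (namespace-agnostic matching is tested, but
against stripped trees), multi-study documents, inconsistent or
free-text-malformed metadata values, live API pagination or rate limits,
and run/analysis objects. Tests against generated bundles demonstrate the
pipeline's contracts, not robustness to arbitrary archive content.

## Numerical and procedural choices

- Character encoding is UTF-8 throughout; serialization is pretty-printed
  with a fixed declaration, so equality checks are byte-level.
- JATS output targets the Journal Publishing 1.2 tag set structurally
  (article root with front/body/back, title and abstract in front
  matter, supplementary CSV referenced via `xlink:href` in back matter,
  never embedded); conformance testing is structural, not DTD validation.
- Degenerate inputs: an empty record list anywhere yields explicitly
  empty sections/tables, never an error; `expand_range("A-A") == [A]`;
  empty/whitespace accession input is the only invalid-input signal.
- Test problem sizes: the XPath oracle-equivalence property runs 12
  seeded bundles (~130 documents) against a brute-force tree walker; the
  round-trip property runs 20 bundle specifications with varied counts
  and missing-field rates. The acceptance script uses the same sizes.

## Known limitations

- Only ENA-dialect documents are supported; GenBank/DDBJ mirrors of the
  same records use different schemas and endpoints.
- Project (`PRJ*`) documents are parsed with the same expressions as
  studies; archive-specific project layouts that place the abstract
  elsewhere would yield an empty Abstract with a logged miss.
- ArrayExpress protocol schemas have varied across releases; the parser
  reads the `protocol/type|text|hardware|software` children and treats
  everything else as out of scope.
- MIxS property classes are not validated against the official term
  lists; the checklist is transported verbatim.
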