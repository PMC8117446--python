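"""Synthetic, internally cross-referenced XML fixture bundles.

The generator emulates the linked document set a real conversion run
fetches: one study document whose XREF_LINK blocks point (by accession
range) at experiment and sample documents, sample documents that link
onward to BioSamples records, and an optional ArrayExpress experiment with
protocol records.  Alongside the documents it returns the ground-truth
records they encode, so parser round-trip tests can compare extraction
output against a known answer — this is what makes the whole pipeline
testable offline.

Determinism: the same :class:`FixtureSpec` always yields byte-identical
documents.  Accessions are allocated sequentially per kind (ERP000001,
ERX000001, …) regardless of seed; the seed drives only the text content.

``missing_field_rate`` drops only fields that are conditionally present in
real records: the FASTQ cross-reference, per-sample BioSample links,
attribute/property units, and protocol hardware/software.  At rate 1.0
every such field is absent from both documents and truth.

Run ``python -m omicspaper.fixtures DIR`` to write the demo bundle to DIR.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from lxml import etree

from .accessions import Accession, Kind
from .parsers import (
    BioSampleRecord,
    ExperimentRecord,
    ProtocolRecord,
    SampleRecord,
    StudyRecord,
)
from .transport import DocKind, RawDocument

__all__ = ["FixtureSpec", "FixtureTruth", "FixtureBundle", "generate",
           "write_fixture_dir", "demo_spec", "DEMO_STUDY_ACCESSION"]

#: Accession of the generated study, stable across seeds.
DEMO_STUDY_ACCESSION = "ERP000001"

_WORDS = (
    "marine", "sediment", "microbial", "community", "coastal", "estuary",
    "metagenome", "survey", "seasonal", "gradient", "benthic", "pelagic",
    "nitrogen", "cycling", "sulfate", "reducing", "archaeal", "bacterial",
    "diversity", "assembly", "amplicon", "shotgun", "profiling", "transect",
    "hydrothermal", "vent", "polar", "fjord", "bloom", "carbon",
)

_LIBRARY_STRATEGIES = ("WGS", "AMPLICON", "RNA-Seq", "WGA")
_PLATFORMS = (
    ("ILLUMINA", "Illumina HiSeq 2500"),
    ("ILLUMINA", "Illumina MiSeq"),
    ("OXFORD_NANOPORE", "MinION"),
    ("PACBIO_SMRT", "Sequel II"),
)
_ATTRIBUTE_TAGS = (
    ("collection date", None),
    ("geographic location (country and/or sea)", None),
    ("depth", "m"),
    ("temperature", "DegreeCelsius"),
    ("environment (biome)", None),
)
_PROPERTY_CLASSES = (
    ("Organism", None),
    ("collection date", None),
    ("geographic location", None),
    ("depth", "m"),
    ("elevation", "m"),
    ("environment (material)", None),
    ("pH", None),
    ("salinity", "psu"),
)
_PROTOCOLS = (
    ("nucleic acid extraction protocol", "QIAGEN DNeasy PowerSoil", None),
    ("nucleic acid library construction protocol", "Illumina HiSeq 2500",
     "bcl2fastq 2.20"),
    ("high throughput sequence alignment protocol", None, "bwa-mem 0.7.17"),
)

_EPOCH = datetime(2021, 5, 13, tzinfo=timezone.utc)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    n_experiments: int = 2
    n_samples: int = 3
    with_arrayexpress: bool = True
    with_biosamples: bool = True
    properties_per_biosample: int = 4
    missing_field_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_experiments < 0 or self.n_samples < 0 \
                or self.properties_per_biosample < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.missing_field_rate <= 1.0:
            raise ValueError("missing_field_rate must be in [0, 1]")


@dataclass(frozen=True)
class FixtureTruth:
    study: StudyRecord
    experiments: tuple[ExperimentRecord, ...]
    samples: tuple[SampleRecord, ...]
    protocols: tuple[ProtocolRecord, ...]
    biosamples: tuple[BioSampleRecord, ...]


@dataclass(frozen=True)
class FixtureBundle:
    documents: tuple[RawDocument, ...]
    truth: FixtureTruth

    def document(self, accession: str, doc_kind: DocKind) -> RawDocument:
        for doc in self.documents:
            if doc.accession.value == accession and doc.doc_kind == doc_kind:
                return doc
        raise KeyError(f"{accession}.{doc_kind.value} not in bundle")


def demo_spec() -> FixtureSpec:
    """The bundled demo conditions: 2 experiments, 3 samples, full links."""
    return FixtureSpec(seed=7, n_experiments=2, n_samples=3,
                       with_arrayexpress=True, with_biosamples=True,
                       properties_per_biosample=4, missing_field_rate=0.0)


def _phrase(rng: random.Random, n: int) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(n))


def _sentence(rng: random.Random, n: int) -> str:
    text = _phrase(rng, n)
    return text[0].upper() + text[1:] + "."


def _serialize(root: etree._Element) -> str:
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _raw(accession: Accession, doc_kind: DocKind, root: etree._Element) -> RawDocument:
    return RawDocument(
        accession=accession,
        doc_kind=doc_kind,
        xml_text=_serialize(root),
        source="fixture",
        retrieved_at=_EPOCH,
    )


def _range_or_single(values: list[str]) -> str:
    if len(values) == 1:
        return values[0]
    return f"{values[0]}-{values[-1]}"


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate a cross-referenced bundle and its ground truth."""
    rng = random.Random(spec.seed)
    drop = lambda: rng.random() < spec.missing_field_rate  # noqa: E731

    study_acc = Accession(DEMO_STUDY_ACCESSION, Kind.STUDY)
    exp_accs = [Accession(f"ERX{i:06d}", Kind.EXPERIMENT)
                for i in range(1, spec.n_experiments + 1)]
    sample_accs = [Accession(f"ERS{i:06d}", Kind.SAMPLE)
                   for i in range(1, spec.n_samples + 1)]
    ae_acc = Accession("E-MTAB-1", Kind.ARRAYEXPRESS) if spec.with_arrayexpress \
        else None

    documents: list[RawDocument] = []

    # --- study document -------------------------------------------------
    title = _sentence(rng, 6)[:-1]
    abstract = _sentence(rng, 25)
    fastq_link = None if drop() else (
        f"ftp.sra.ebi.ac.uk/vol1/fastq/{study_acc.value}"
    )
    xrefs: list[tuple[str, str]] = []
    if fastq_link:
        xrefs.append(("ENA-FASTQ-FILES", fastq_link))
    if exp_accs:
        xrefs.append(("ENA-EXPERIMENT", _range_or_single([a.value for a in exp_accs])))
    if sample_accs:
        xrefs.append(("ENA-SAMPLE", _range_or_single([a.value for a in sample_accs])))
    if ae_acc is not None:
        xrefs.append(("ARRAYEXPRESS", ae_acc.value))

    study_root = etree.Element("STUDY_SET")
    study_el = etree.SubElement(study_root, "STUDY", accession=study_acc.value)
    idents = etree.SubElement(study_el, "IDENTIFIERS")
    etree.SubElement(idents, "PRIMARY_ID").text = study_acc.value
    descriptor = etree.SubElement(study_el, "DESCRIPTOR")
    etree.SubElement(descriptor, "STUDY_TITLE").text = title
    etree.SubElement(study_el, "abstract").text = abstract
    links = etree.SubElement(study_el, "STUDY_LINKS")
    for db, xid in xrefs:
        link = etree.SubElement(links, "STUDY_LINK")
        xref = etree.SubElement(link, "XREF_LINK")
        etree.SubElement(xref, "DB").text = db
        etree.SubElement(xref, "ID").text = xid
    documents.append(_raw(study_acc, DocKind.STUDY, study_root))

    truth_study = StudyRecord(
        accession=study_acc, title=title, abstract=abstract,
        xrefs=tuple(xrefs), fastq_link=fastq_link, arrayexpress_id=ae_acc,
    )

    # --- experiment documents -------------------------------------------
    truth_experiments = []
    for acc in exp_accs:
        strategy = rng.choice(_LIBRARY_STRATEGIES)
        group, model = rng.choice(_PLATFORMS)
        design = _sentence(rng, 8)
        root = etree.Element("EXPERIMENT_SET")
        exp = etree.SubElement(root, "EXPERIMENT", accession=acc.value)
        design_el = etree.SubElement(exp, "DESIGN")
        etree.SubElement(design_el, "DESIGN_DESCRIPTION").text = design
        lib = etree.SubElement(design_el, "LIBRARY_DESCRIPTOR")
        etree.SubElement(lib, "LIBRARY_STRATEGY").text = strategy
        platform = etree.SubElement(exp, "PLATFORM")
        family = etree.SubElement(platform, group)
        etree.SubElement(family, "INSTRUMENT_MODEL").text = model
        documents.append(_raw(acc, DocKind.EXPERIMENT, root))
        truth_experiments.append(
            ExperimentRecord(accession=acc, library_strategy=strategy,
                             platform_group=group, instrument_model=model,
                             design_description=design)
        )

    # --- sample documents (+ BioSample links) ---------------------------
    truth_samples = []
    biosample_accs: list[Accession] = []
    for i, acc in enumerate(sample_accs, start=1):
        description = _sentence(rng, 10)
        n_attrs = rng.randint(1, 3)
        attributes = []
        for _ in range(n_attrs):
            tag, unit = rng.choice(_ATTRIBUTE_TAGS)
            value = _phrase(rng, 2)
            if unit is not None and drop():
                unit = None
            attributes.append((tag, value, unit))
        biosample_id = None
        if spec.with_biosamples and not drop():
            biosample_id = Accession(f"SAMEA{i:07d}", Kind.BIOSAMPLE)
            biosample_accs.append(biosample_id)

        root = etree.Element("SAMPLE_SET")
        sample = etree.SubElement(root, "SAMPLE", accession=acc.value)
        idents = etree.SubElement(sample, "IDENTIFIERS")
        etree.SubElement(idents, "PRIMARY_ID").text = acc.value
        if biosample_id is not None:
            ext = etree.SubElement(idents, "EXTERNAL_ID", namespace="BioSample")
            ext.text = biosample_id.value
        etree.SubElement(sample, "DESCRIPTION").text = description
        attrs_el = etree.SubElement(sample, "SAMPLE_ATTRIBUTES")
        for tag, value, unit in attributes:
            attr = etree.SubElement(attrs_el, "SAMPLE_ATTRIBUTE")
            etree.SubElement(attr, "TAG").text = tag
            etree.SubElement(attr, "VALUE").text = value
            if unit is not None:
                etree.SubElement(attr, "UNITS").text = unit
        documents.append(_raw(acc, DocKind.SAMPLE, root))
        truth_samples.append(
            SampleRecord(accession=acc, description=description,
                         attributes=tuple(attributes), biosample_id=biosample_id)
        )

    # --- BioSamples documents -------------------------------------------
    truth_biosamples = []
    for acc in biosample_accs:
        properties = []
        for _ in range(spec.properties_per_biosample):
            prop_class, unit = rng.choice(_PROPERTY_CLASSES)
            value = _phrase(rng, 2)
            if unit is not None and drop():
                unit = None
            properties.append((prop_class, value, unit))
        root = etree.Element("BioSample", accession=acc.value)
        for prop_class, value, unit in properties:
            prop = etree.SubElement(root, "Property")
            prop.set("class", prop_class)
            qualified = etree.SubElement(prop, "QualifiedValue")
            etree.SubElement(qualified, "Value").text = value
            if unit is not None:
                etree.SubElement(qualified, "Unit").text = unit
        documents.append(_raw(acc, DocKind.BIOSAMPLE, root))
        truth_biosamples.append(
            BioSampleRecord(accession=acc, properties=tuple(properties))
        )

    # --- ArrayExpress experiment + protocols ----------------------------
    truth_protocols = []
    if ae_acc is not None:
        exp_root = etree.Element("experiments")
        exp_el = etree.SubElement(exp_root, "experiment")
        etree.SubElement(exp_el, "accession").text = ae_acc.value
        etree.SubElement(exp_el, "name").text = title
        documents.append(_raw(ae_acc, DocKind.ARRAYEXPRESS_EXPERIMENT, exp_root))

        proto_root = etree.Element("protocols")
        for proto_type, hardware, software in _PROTOCOLS[:2]:
            text = _sentence(rng, 12)
            if hardware is not None and drop():
                hardware = None
            if software is not None and drop():
                software = None
            proto = etree.SubElement(proto_root, "protocol")
            etree.SubElement(proto, "type").text = proto_type
            etree.SubElement(proto, "text").text = text
            if hardware is not None:
                etree.SubElement(proto, "hardware").text = hardware
            if software is not None:
                etree.SubElement(proto, "software").text = software
            truth_protocols.append(
                ProtocolRecord(protocol_type=proto_type, text=text,
                               hardware=hardware, software=software)
            )
        documents.append(_raw(ae_acc, DocKind.ARRAYEXPRESS_PROTOCOL, proto_root))

    truth = FixtureTruth(
        study=truth_study,
        experiments=tuple(truth_experiments),
        samples=tuple(truth_samples),
        protocols=tuple(truth_protocols),
        biosamples=tuple(truth_biosamples),
    )
    return FixtureBundle(documents=tuple(documents), truth=truth)


def write_fixture_dir(bundle: FixtureBundle, path: str | Path) -> list[Path]:
    """Write a bundle to a directory in the transport fixture layout.

    Files are named ``<accession>.<doc_kind>.xml``; re-reading them through
    the fixture backend reproduces ``xml_text`` exactly.
    """
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for doc in bundle.documents:
        target = directory / f"{doc.name}.xml"
        target.write_text(doc.xml_text, "utf-8")
        written.append(target)
    return written


def _main() -> None:  # pragma: no cover - convenience entry point
    import sys

    target = sys.argv[1] if len(sys.argv) > 1 else "demo_fixture"
    files = write_fixture_dir(generate(demo_spec()), target)
    print(f"wrote {len(files)} fixture documents to {target}")


if __name__ == "__main__":  # pragma: no cover
    _main()
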