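"""Manuscript assembly: the omics data paper section template.

The template is a fixed hierarchy of sections.  A small subset can be
auto-populated from repository metadata — Abstract, Methods/Sampling,
Methods/Sample processing/Technologies used, Data resources, and
Supplementary material — while the remaining sections are emitted as
placeholders carrying guidance text for the authors.  Methods and Data
resources are mandatory: :func:`validate` flags a manuscript in which either
is empty or placeholder-only.

The supplementary MIxS checklist is a protected component: once attached it
cannot be edited or removed through the manuscript API; the only way to
change it is :func:`reimport_biosamples`, which refetches the BioSamples
records from the source and re-pivots the table, leaving every other
section untouched.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .accessions import Accession
from .checklist import ChecklistRow, ChecklistTable, pivot
from .parsers import (
    XPATH_REGISTRY,
    BioSampleRecord,
    ExperimentRecord,
    ProtocolRecord,
    SampleRecord,
    StudyRecord,
    parse_biosample,
)
from .transport import DocKind, MissingRecordError

__all__ = [
    "PLACEHOLDER_MARKER",
    "SectionSpec",
    "Section",
    "Manuscript",
    "Violation",
    "section_registry",
    "build_manuscript",
    "validate",
    "reimport_biosamples",
]

logger = logging.getLogger(__name__)

PLACEHOLDER_MARKER = "[TO BE COMPLETED BY AUTHORS]"


@dataclass(frozen=True)
class SectionSpec:
    """Template registry entry. ``section_id`` doubles as the JATS sec-type."""

    section_id: str
    title: str
    parent: str | None
    auto_fillable: bool
    mandatory: bool
    guidance: str


# (title, auto, mandatory, guidance, children). Two sections share the title
# "Technologies used" (under Sampling and under Sample processing); they are
# addressed by path, never by id.
_TEMPLATE = (
    ("Abstract", True, False,
     "Summary of the value of the study, the experimental design, and the dataset itself.",
     ()),
    ("Introduction", False, False,
     "Why the study was undertaken and its context.",
     (
         ("Value of the dataset", False, False,
          "Put the dataset into perspective for its intended audiences.",
          (
              ("Scientific value", False, False,
               "What the dataset offers the scientific community, including any "
               "larger sequencing project it belongs to.",
               ()),
              ("Societal value", False, False,
               "What the dataset offers communities beyond science.",
               ()),
          )),
     )),
    ("Methods", False, True,
     "How the physical material was collected, processed, and turned into a dataset.",
     (
         ("Sampling", True, False,
          "When, where, and how the physical material was collected.",
          (
              ("Environmental profile", False, False,
               "Environmental characteristics of the sampling locations "
               "(habitat, season, conditions).",
               ()),
              ("Geographic range", False, False,
               "Geographic extent of the sampling (coordinates, regions).",
               ()),
              ("Technologies used", False, False,
               "Sampling methods and equipment.",
               ()),
          )),
         ("Sample processing", False, False,
          "Laboratory procedures that turned each physical sample into its "
          "digital footprint.",
          (
              ("Technologies used", True, False,
               "Library strategies, sequencing platforms, and laboratory protocols.",
               ()),
          )),
         ("Data processing", False, False,
          "Steps that transformed the raw dataset into the published one "
          "(filtering, normalization).",
          ()),
     )),
    ("Biodiversity profile", False, False,
     "The biological entities the study focuses on.",
     (
         ("Target", False, False,
          "The molecular target of the study (DNA, RNA, protein).",
          ()),
         ("Taxonomic range", False, False,
          "Taxonomy of the studied organism(s) or taxonomic composition of the sample.",
          ()),
         ("Functional range", False, False,
          "Range of biological functions studied, if relevant.",
          ()),
         ("Traits", False, False,
          "Specific traits studied (e.g. pathogenicity), if relevant.",
          ()),
     )),
    ("Data resources", True, True,
     "Links to the dataset(s), accession numbers, and data formats.",
     ()),
    ("Data statistics", False, False,
     "Quantitative and qualitative descriptors of the dataset (read depth, "
     "coverage, base ratios).",
     ()),
    ("Caveats and limitations", False, False,
     "What could be improved and what to consider when reusing the data.",
     ()),
    ("Usage rights", False, False,
     "Rights and licenses under which the data can be used.",
     ()),
    ("Supplementary material", True, False,
     "MIxS checklists of the linked BioSamples, attached as a CSV table.",
     ()),
)


def section_registry() -> list[SectionSpec]:
    """The template as a flat list of specs in document order."""
    specs: list[SectionSpec] = []

    def walk(nodes, parent: str | None) -> None:
        for title, auto, mandatory, guidance, children in nodes:
            specs.append(SectionSpec(title, title, parent, auto, mandatory, guidance))
            walk(children, title)

    walk(_TEMPLATE, None)
    return specs


@dataclass
class Section:
    """One manuscript section: spec, content blocks, and children."""

    spec: SectionSpec
    blocks: list[str] = field(default_factory=list)
    provenance: str = "placeholder"  # "auto" | "placeholder"
    children: list["Section"] = field(default_factory=list)

    def iter(self) -> Iterator["Section"]:
        yield self
        for child in self.children:
            yield from child.iter()


@dataclass(frozen=True)
class Violation:
    section_id: str
    message: str


class Manuscript:
    """Ordered section tree plus the protected supplementary checklist.

    The supplementary table is read-only: there is no setter, and the only
    operation that replaces it is :func:`reimport_biosamples`, which returns
    a new manuscript.
    """

    def __init__(
        self,
        study_accession: Accession,
        title: str,
        sections: list[Section],
        supplementary: ChecklistTable | None,
        provenance_log: list[tuple[str, str, str]],
        biosample_accessions: list[Accession],
        warnings: list[str],
    ):
        self.study_accession = study_accession
        self.title = title
        self.sections = sections
        self.__supplementary = supplementary
        self.provenance_log = list(provenance_log)
        self.biosample_accessions = list(biosample_accessions)
        self.warnings = list(warnings)

    @property
    def supplementary(self) -> ChecklistTable | None:
        return self.__supplementary

    def iter_sections(self) -> Iterator[Section]:
        for section in self.sections:
            yield from section.iter()

    def find(self, *path: str) -> Section:
        """Locate a section by title path, e.g. ``find("Methods", "Sampling")``."""
        nodes = self.sections
        section: Section | None = None
        for title in path:
            section = next((s for s in nodes if s.spec.title == title), None)
            if section is None:
                raise KeyError(f"no section at path {path}")
            nodes = section.children
        assert section is not None
        return section


def _build_tree(nodes=_TEMPLATE, parent: str | None = None) -> list[Section]:
    sections = []
    for title, auto, mandatory, guidance, children in nodes:
        spec = SectionSpec(title, title, parent, auto, mandatory, guidance)
        section = Section(spec=spec, provenance="auto" if auto else "placeholder")
        if not auto:
            section.blocks = [f"{guidance} {PLACEHOLDER_MARKER}"]
        section.children = _build_tree(children, title)
        sections.append(section)
    return sections


def _dedup(items: Sequence[str]) -> list[str]:
    """Order-preserving, case-sensitive exact-match deduplication."""
    seen: set[str] = set()
    out = []
    for item in items:
        if item and item not in seen:
            seen.add(item)
            out.append(item)
    return out


def _protocol_line(p: ProtocolRecord) -> str:
    line = f"Protocol ({p.protocol_type}): {p.text}".rstrip(": ").strip()
    extras = []
    if p.hardware:
        extras.append(f"hardware: {p.hardware}")
    if p.software:
        extras.append(f"software: {p.software}")
    if extras:
        line += f" [{'; '.join(extras)}]"
    return line


def build_manuscript(
    study: StudyRecord,
    experiments: Sequence[ExperimentRecord] = (),
    samples: Sequence[SampleRecord] = (),
    protocols: Sequence[ProtocolRecord] = (),
    biosamples: Sequence[BioSampleRecord] = (),
) -> Manuscript:
    """Assemble a manuscript from parsed records.

    Auto-fillable sections draw on their template source fields; everything
    else becomes a guidance placeholder.  Empty sources leave the auto
    section explicitly empty and log a miss — nothing is fabricated.
    """
    sections = _build_tree()
    log: list[tuple[str, str, str]] = []
    warnings: list[str] = []
    m = Manuscript(
        study_accession=study.accession,
        title=study.title or f"Omics data paper for {study.accession.value}",
        sections=sections,
        supplementary=None,
        provenance_log=log,
        biosample_accessions=[],
        warnings=warnings,
    )
    study_doc = f"{study.accession.value}.{DocKind.STUDY.value}"

    # Abstract
    abstract = m.find("Abstract")
    if study.abstract:
        abstract.blocks = [study.abstract]
        log.append(("Abstract", study_doc, XPATH_REGISTRY["study_abstract"]))
    else:
        warnings.append("empty-source:Abstract")
        logger.info("no abstract in %s; Abstract left empty", study_doc)

    # Methods / Sampling — grouped per sample, ordered by accession
    sampling = m.find("Methods", "Sampling")
    ordered_samples = sorted(samples, key=lambda s: (s.accession.number or 0,
                                                     s.accession.value))
    for sample in ordered_samples:
        doc = f"{sample.accession.value}.{DocKind.SAMPLE.value}"
        if sample.description:
            sampling.blocks.append(f"Sample {sample.accession.value}: "
                                   f"{sample.description}")
            log.append(("Sampling", doc, XPATH_REGISTRY["sample_description"]))
        for tag, value, units in sample.attributes:
            line = f"{sample.accession.value} — {tag}: {value}"
            if units:
                line += f" ({units})"
            sampling.blocks.append(line)
            log.append(("Sampling", doc, XPATH_REGISTRY["sample_attribute"]))
    if not sampling.blocks:
        warnings.append("empty-source:Sampling")

    # Methods / Sample processing / Technologies used
    tech = m.find("Methods", "Sample processing", "Technologies used")
    strategies = _dedup([e.library_strategy for e in experiments])
    platforms = _dedup([e.platform_text for e in experiments])
    for strategy in strategies:
        tech.blocks.append(f"Library strategy: {strategy}")
    for platform in platforms:
        tech.blocks.append(f"Platform: {platform}")
    for exp in experiments:
        doc = f"{exp.accession.value}.{DocKind.EXPERIMENT.value}"
        if exp.library_strategy:
            log.append(("Technologies used", doc, XPATH_REGISTRY["library_strategy"]))
        if exp.platform_text:
            log.append(("Technologies used", doc, XPATH_REGISTRY["platform"]))
    for protocol in protocols:
        tech.blocks.append(_protocol_line(protocol))
        for key in ("protocol_type", "protocol_text", "protocol_hardware",
                    "protocol_software"):
            log.append(("Technologies used", "arrayexpress_protocol",
                        XPATH_REGISTRY[key]))
    if not tech.blocks:
        warnings.append("empty-source:Technologies used")

    # Data resources — FASTQ link first, then experiment and sample accessions
    resources = m.find("Data resources")
    if study.fastq_link:
        resources.blocks.append(f"FASTQ files: {study.fastq_link}")
        log.append(("Data resources", study_doc, XPATH_REGISTRY["fastq_files_link"]))
    if experiments:
        accs = ", ".join(e.accession.value for e in experiments)
        resources.blocks.append(f"Experiment accessions: {accs}")
        log.append(("Data resources", study_doc, XPATH_REGISTRY["xref_link"]))
    if samples:
        accs = ", ".join(s.accession.value for s in ordered_samples)
        resources.blocks.append(f"Sample accessions: {accs}")
        log.append(("Data resources", study_doc, XPATH_REGISTRY["xref_link"]))
    if not resources.blocks:
        warnings.append("empty-source:Data resources")

    # Supplementary material — present iff at least one BioSample record
    supp = m.find("Supplementary material")
    table: ChecklistTable | None = None
    if biosamples:
        table = pivot(list(biosamples))
        supp.blocks = [
            f"MIxS checklist: {len(table)} properties across "
            f"{len(biosamples)} BioSamples record(s), attached as "
            f"{study.accession.value}.mixs_checklist.csv."
        ]
        for record in biosamples:
            log.append(
                ("Supplementary material",
                 f"{record.accession.value}.{DocKind.BIOSAMPLE.value}",
                 XPATH_REGISTRY["biosample_property"])
            )
        for sample in ordered_samples:
            if sample.biosample_id is not None:
                log.append(
                    ("Supplementary material",
                     f"{sample.accession.value}.{DocKind.SAMPLE.value}",
                     XPATH_REGISTRY["biosample_external_id"])
                )
        m.biosample_accessions = [r.accession for r in biosamples]
    else:
        warnings.append("no-biosamples")

    # Rebuild with the (immutable) supplementary attached.
    return Manuscript(
        study_accession=m.study_accession,
        title=m.title,
        sections=m.sections,
        supplementary=table,
        provenance_log=log,
        biosample_accessions=m.biosample_accessions,
        warnings=warnings,
    )


def _has_auto_content(section: Section) -> bool:
    return any(s.provenance == "auto" and s.blocks for s in section.iter())


def validate(m: Manuscript) -> list[Violation]:
    """Check mandatory sections; an empty list means submission-ready.

    A mandatory section violates when its entire subtree holds no
    auto-populated content — placeholder guidance does not count.
    """
    violations = []
    for section in m.sections:
        if section.spec.mandatory and not _has_auto_content(section):
            violations.append(
                Violation(
                    section_id=section.spec.section_id,
                    message=f"mandatory section {section.spec.title!r} is empty "
                            f"or placeholder-only",
                )
            )
    return violations


def reimport_biosamples(m: Manuscript, backend) -> Manuscript:
    """Refetch BioSamples records and re-pivot the supplementary table.

    Returns a new manuscript in which only the supplementary table (and the
    Supplementary material summary block) may differ; all other sections are
    carried over unchanged.  A biosample that has gone missing upstream is
    reported as a warning and its stale rows are retained, so the table is
    never silently truncated.
    """
    if not m.biosample_accessions:
        raise ValueError("manuscript has no recorded BioSamples accessions")
    stale_rows: dict[str, list[ChecklistRow]] = {}
    if m.supplementary is not None:
        for row in m.supplementary.rows:
            stale_rows.setdefault(row.biosample_accession, []).append(row)
    rows: list[ChecklistRow] = []
    warnings = [w for w in m.warnings if not w.startswith("reimport-")]
    n_records = 0
    for accession in m.biosample_accessions:
        try:
            doc = backend.fetch(accession, DocKind.BIOSAMPLE)
            record = parse_biosample(doc)
            rows.extend(pivot([record]).rows)
            n_records += 1
        except MissingRecordError:
            warnings.append(f"reimport-missing-record:{accession.value}")
            logger.warning(
                "biosample %s missing on re-import; keeping stale rows",
                accession.value,
            )
            rows.extend(stale_rows.get(accession.value, []))
            n_records += 1
    table = ChecklistTable(rows=tuple(rows))
    sections = copy.deepcopy(m.sections)
    new = Manuscript(
        study_accession=m.study_accession,
        title=m.title,
        sections=sections,
        supplementary=table,
        provenance_log=list(m.provenance_log),
        biosample_accessions=list(m.biosample_accessions),
        warnings=warnings,
    )
    supp = new.find("Supplementary material")
    supp.blocks = [
        f"MIxS checklist: {len(table)} properties across "
        f"{n_records} BioSamples record(s), attached as "
        f"{m.study_accession.value}.mixs_checklist.csv."
    ]
    return new
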