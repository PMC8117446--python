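"""XPath-driven extraction of typed records from ENA-dialect XML documents.

Each record field is populated through one expression in
:data:`XPATH_REGISTRY`, a declarative mapping kept as data so the extraction
surface is auditable in one place.  Expressions are evaluated
namespace-agnostically (ENA dialects vary in default-namespace usage), and
the returned text values follow XPath string-value semantics: concatenated
descendant text for element matches, the value itself for attribute matches,
always in document order.

The record types mirror the ENA metadata model: a study/project document is
the entry point and cross-references (XREF_LINK blocks) name the linked
experiments, samples, and an optional ArrayExpress experiment; sample
documents link onward to BioSamples via an EXTERNAL_ID in the BioSample
namespace; BioSamples documents carry the MIxS checklist as Property
elements with a ``class`` attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from lxml import etree

from .accessions import (
    Accession,
    Kind,
    MalformedRangeError,
    classify,
    expand_range,
)
from .transport import DocKind, MalformedPayloadError, RawDocument

__all__ = [
    "XPATH_REGISTRY",
    "BadExpressionError",
    "KindMismatchError",
    "StudyRecord",
    "ExperimentRecord",
    "SampleRecord",
    "ProtocolRecord",
    "BioSampleRecord",
    "LinkSet",
    "xpath_extract",
    "xpath_nodes",
    "parse_study",
    "parse_experiment",
    "parse_sample",
    "parse_biosample",
    "parse_arrayexpress_protocols",
    "resolve_links",
]

logger = logging.getLogger(__name__)

#: Declarative field → XPath mapping. The values are the exact source-field
#: expressions the manuscript template draws on, plus a few plumbing entries
#: (title, xref ids) needed to assemble records.
XPATH_REGISTRY: dict[str, str] = {
    "study_abstract": "//abstract",
    "study_title": "//STUDY_TITLE",
    "xref_link": "//XREF_LINK",
    "fastq_files_link": "//XREF_LINK/ID[../DB = 'ENA-FASTQ-FILES']",
    "library_strategy": "//EXPERIMENT/DESIGN/LIBRARY_DESCRIPTOR/LIBRARY_STRATEGY",
    "platform": "//EXPERIMENT/PLATFORM",
    "design_description": "//EXPERIMENT/DESIGN/DESIGN_DESCRIPTION",
    "sample_description": "//SAMPLE/DESCRIPTION",
    "sample_attribute": "//SAMPLE/SAMPLE_ATTRIBUTES/SAMPLE_ATTRIBUTE",
    "biosample_external_id": "//SAMPLE/IDENTIFIERS/EXTERNAL_ID[@namespace = 'BioSample']",
    "biosample_property": "//Property[@class]",
    "protocol_type": "protocol/type",
    "protocol_text": "protocol/text",
    "protocol_hardware": "protocol/hardware",
    "protocol_software": "protocol/software",
}


class BadExpressionError(ValueError):
    """Raised for syntactically invalid XPath expressions."""


class KindMismatchError(ValueError):
    """Raised when a parser is handed a document of the wrong kind."""


@dataclass(frozen=True)
class StudyRecord:
    accession: Accession
    title: str
    abstract: str
    xrefs: tuple[tuple[str, str], ...]  # (db label, id-or-range string)
    fastq_link: str | None
    arrayexpress_id: Accession | None


@dataclass(frozen=True)
class ExperimentRecord:
    accession: Accession
    library_strategy: str
    platform_group: str
    instrument_model: str
    design_description: str | None = None

    @property
    def platform_text(self) -> str:
        """Readable platform string: family name + instrument model."""
        return f"{self.platform_group} {self.instrument_model}".strip()


@dataclass(frozen=True)
class SampleRecord:
    accession: Accession
    description: str
    attributes: tuple[tuple[str, str, str | None], ...]  # (tag, value, units)
    biosample_id: Accession | None


@dataclass(frozen=True)
class ProtocolRecord:
    protocol_type: str
    text: str
    hardware: str | None = None
    software: str | None = None


@dataclass(frozen=True)
class BioSampleRecord:
    accession: Accession
    properties: tuple[tuple[str, str, str | None], ...]  # (class, value, unit)


@dataclass(frozen=True)
class LinkSet:
    """Accessions a study document links to, after range expansion."""

    experiments: tuple[Accession, ...] = ()
    samples: tuple[Accession, ...] = ()
    arrayexpress: Accession | None = None


def _strip_namespaces(root: etree._Element) -> None:
    for el in root.iter():
        if isinstance(el.tag, str) and "}" in el.tag:
            el.tag = el.tag.split("}", 1)[1]
        for key in list(el.attrib):
            if "}" in key:
                el.attrib[key.split("}", 1)[1]] = el.attrib.pop(key)
    etree.cleanup_namespaces(root)


def _tree(doc: RawDocument) -> etree._Element:
    try:
        root = etree.fromstring(doc.xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise MalformedPayloadError(f"{doc.name}: {exc}")
    _strip_namespaces(root)
    return root


def _require_kind(doc: RawDocument, *allowed: DocKind) -> None:
    if doc.doc_kind not in allowed:
        raise KindMismatchError(
            f"{doc.name}: expected doc kind in "
            f"{[k.value for k in allowed]}, got {doc.doc_kind.value!r}"
        )


def xpath_nodes(root: etree._Element, expression: str) -> list:
    """Evaluate *expression* against an element, returning raw matches."""
    try:
        compiled = etree.XPath(expression)
    except etree.XPathSyntaxError as exc:
        raise BadExpressionError(f"invalid XPath {expression!r}: {exc}")
    result = compiled(root)
    if not isinstance(result, list):  # numeric/boolean XPath results
        return [result]
    return result


def xpath_extract(doc: RawDocument, expression: str) -> list[str]:
    """Extract document-order text values matched by an XPath expression.

    Element matches contribute their string-value (concatenated descendant
    text); attribute matches contribute the attribute value.  An expression
    matching nothing returns an empty list, never an error.
    """
    out: list[str] = []
    for item in xpath_nodes(_tree(doc), expression):
        if isinstance(item, etree._Element):
            out.append("".join(item.itertext()))
        else:
            out.append(str(item))
    return out


def _first_text(root: etree._Element, expression: str) -> str | None:
    nodes = xpath_nodes(root, expression)
    if not nodes:
        return None
    if len(nodes) > 1:
        logger.warning(
            "expression %r matched %d nodes; first match wins", expression, len(nodes)
        )
    item = nodes[0]
    text = "".join(item.itertext()) if isinstance(item, etree._Element) else str(item)
    return text.strip()


def parse_study(doc: RawDocument) -> StudyRecord:
    """Parse a study or project document: abstract plus cross-references."""
    _require_kind(doc, DocKind.STUDY, DocKind.PROJECT)
    root = _tree(doc)
    title = _first_text(root, XPATH_REGISTRY["study_title"]) or _first_text(
        root, "//TITLE"
    ) or ""
    abstract = _first_text(root, XPATH_REGISTRY["study_abstract"]) or ""
    xrefs: list[tuple[str, str]] = []
    for node in xpath_nodes(root, XPATH_REGISTRY["xref_link"]):
        db = node.findtext("DB") or ""
        xid = node.findtext("ID") or ""
        if db.strip():
            xrefs.append((db.strip(), xid.strip()))
    fastq_link = _first_text(root, XPATH_REGISTRY["fastq_files_link"]) or None
    arrayexpress_id = None
    for _db, xid in xrefs:
        if not xid:
            continue
        candidate = classify(xid)
        if candidate.kind is Kind.ARRAYEXPRESS:
            arrayexpress_id = candidate
            break
    return StudyRecord(
        accession=doc.accession,
        title=title,
        abstract=abstract,
        xrefs=tuple(xrefs),
        fastq_link=fastq_link,
        arrayexpress_id=arrayexpress_id,
    )


def parse_experiment(doc: RawDocument) -> ExperimentRecord:
    """Parse an experiment document: library strategy and platform."""
    _require_kind(doc, DocKind.EXPERIMENT)
    root = _tree(doc)
    strategy = _first_text(root, XPATH_REGISTRY["library_strategy"]) or ""
    platform_group = ""
    instrument_model = ""
    platforms = xpath_nodes(root, XPATH_REGISTRY["platform"])
    if platforms:
        platform = platforms[0]
        children = [c for c in platform if isinstance(c.tag, str)]
        if children:
            platform_group = children[0].tag
            instrument_model = (children[0].findtext(".//INSTRUMENT_MODEL") or "").strip()
    design = _first_text(root, XPATH_REGISTRY["design_description"])
    return ExperimentRecord(
        accession=doc.accession,
        library_strategy=strategy,
        platform_group=platform_group,
        instrument_model=instrument_model,
        design_description=design or None,
    )


def parse_sample(doc: RawDocument) -> SampleRecord:
    """Parse a sample document: description, attribute triples, BioSample link."""
    _require_kind(doc, DocKind.SAMPLE)
    root = _tree(doc)
    description = _first_text(root, XPATH_REGISTRY["sample_description"]) or ""
    attributes: list[tuple[str, str, str | None]] = []
    for node in xpath_nodes(root, XPATH_REGISTRY["sample_attribute"]):
        tag = (node.findtext("TAG") or "").strip()
        value = (node.findtext("VALUE") or "").strip()
        units = node.findtext("UNITS")
        attributes.append((tag, value, units.strip() if units is not None else None))
    biosample_text = _first_text(root, XPATH_REGISTRY["biosample_external_id"])
    biosample_id = None
    if biosample_text:
        candidate = classify(biosample_text)
        if candidate.kind is Kind.BIOSAMPLE:
            biosample_id = candidate
        else:
            logger.warning(
                "%s: BioSample external id %r does not look like a SAM* accession",
                doc.name, biosample_text,
            )
    return SampleRecord(
        accession=doc.accession,
        description=description,
        attributes=tuple(attributes),
        biosample_id=biosample_id,
    )


def parse_biosample(doc: RawDocument) -> BioSampleRecord:
    """Parse a BioSamples document into (class, value, unit) property rows.

    One row per (Property, Value) pair: a Property carrying several
    QualifiedValue children yields one row each, the unit taken from the
    Unit element beside that value when present.
    """
    _require_kind(doc, DocKind.BIOSAMPLE)
    root = _tree(doc)
    properties: list[tuple[str, str, str | None]] = []
    for node in xpath_nodes(root, XPATH_REGISTRY["biosample_property"]):
        prop_class = node.get("class", "").strip()
        if not prop_class:
            continue
        values = node.findall(".//Value")
        if values:
            for value_el in values:
                parent = value_el.getparent()
                unit = parent.findtext("Unit") if parent is not None else None
                properties.append(
                    (
                        prop_class,
                        (value_el.text or "").strip(),
                        unit.strip() if unit is not None else None,
                    )
                )
        else:
            properties.append((prop_class, "".join(node.itertext()).strip(), None))
    return BioSampleRecord(accession=doc.accession, properties=tuple(properties))


def parse_arrayexpress_protocols(doc: RawDocument) -> list[ProtocolRecord]:
    """Parse an ArrayExpress protocols document into protocol records.

    A protocol with all four of type/text/hardware/software empty is dropped.
    """
    _require_kind(doc, DocKind.ARRAYEXPRESS_PROTOCOL)
    root = _tree(doc)
    records: list[ProtocolRecord] = []
    for node in xpath_nodes(root, "protocol"):
        fields = {
            key: node.findtext(XPATH_REGISTRY[f"protocol_{key}"].split("/", 1)[1])
            for key in ("type", "text", "hardware", "software")
        }
        fields = {k: v.strip() if v is not None else None for k, v in fields.items()}
        if not any(fields.values()):
            continue
        records.append(
            ProtocolRecord(
                protocol_type=fields["type"] or "",
                text=fields["text"] or "",
                hardware=fields["hardware"] or None,
                software=fields["software"] or None,
            )
        )
    return records


#: XREF_LINK DB labels that never carry experiment/sample accession ranges.
_NON_OBJECT_XREF_DBS = {"ENA-FASTQ-FILES", "ENA-SUBMISSION", "ENA-RUN", "PUBMED"}


def resolve_links(study: StudyRecord) -> LinkSet:
    """Resolve a study's cross-references into linked-object accessions.

    Hyphenated ranges are expanded, duplicates removed, and each identifier
    classified; experiment and sample accessions are routed to their lists
    and an ArrayExpress id (E-XXXX-n) is recognized wherever it appears.
    Malformed ranges under an ENA object label propagate with that label
    attached; unrecognized identifiers under other labels are skipped.
    """
    experiments: dict[str, Accession] = {}
    samples: dict[str, Accession] = {}
    arrayexpress: Accession | None = None
    for db, xid in study.xrefs:
        if not xid or db in _NON_OBJECT_XREF_DBS:
            continue
        single = classify(xid)
        if single.kind is Kind.ARRAYEXPRESS:
            if arrayexpress is None:
                arrayexpress = single
            continue
        is_object_label = db.upper() in ("ENA-EXPERIMENT", "ENA-SAMPLE")
        try:
            expanded = expand_range(xid)
        except (MalformedRangeError, ValueError) as exc:
            if is_object_label:
                raise MalformedRangeError(f"xref {db!r}: {exc}") from exc
            logger.debug("skipping unparseable xref (%s, %s)", db, xid)
            continue
        for acc in expanded:
            if acc.kind is Kind.EXPERIMENT:
                experiments[acc.value] = acc
            elif acc.kind is Kind.SAMPLE:
                samples[acc.value] = acc
    order = lambda a: (a.number or 0, a.value)  # noqa: E731
    return LinkSet(
        experiments=tuple(sorted(experiments.values(), key=order)),
        samples=tuple(sorted(samples.values(), key=order)),
        arrayexpress=arrayexpress,
    )
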