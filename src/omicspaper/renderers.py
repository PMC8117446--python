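"""Manuscript serialization to JATS XML and standalone HTML.

The JATS output targets the Journal Publishing 1.2 tag set structurally:
one ``article`` root with ``front``/``body``/``back``, the article title
and abstract in the front matter, and every template section as a ``sec``
element whose ``sec-type`` attribute is the section id (the Methods section
literally carries ``sec-type="Methods"``).  The supplementary CSV is
referenced from the back matter, not embedded.  Both renderings are
deterministic for a given manuscript and escape all content, so every
auto-populated fragment survives verbatim modulo XML/HTML escaping.
"""

from __future__ import annotations

from dataclasses import dataclass

from lxml import etree
from lxml.builder import ElementMaker

from .assembler import Manuscript, Section
from .checklist import HEADER

__all__ = ["JatsDocument", "render_jats", "render_html", "supplementary_filename"]

XLINK_NS = "http://www.w3.org/1999/xlink"


@dataclass(frozen=True)
class JatsDocument:
    xml_text: str


def supplementary_filename(m: Manuscript) -> str:
    return f"{m.study_accession.value}.mixs_checklist.csv"


def _jats_sec(section: Section) -> etree._Element:
    sec = etree.Element("sec", {"sec-type": section.spec.section_id})
    title = etree.SubElement(sec, "title")
    title.text = section.spec.title
    for block in section.blocks:
        p = etree.SubElement(sec, "p")
        p.text = block
    for child in section.children:
        sec.append(_jats_sec(child))
    return sec


def render_jats(m: Manuscript) -> JatsDocument:
    """Render a manuscript to a JATS XML document."""
    E = ElementMaker(nsmap={"xlink": XLINK_NS})
    article = E(
        "article",
        {"article-type": "data-paper", "dtd-version": "1.2"},
    )

    front = etree.SubElement(article, "front")
    meta = etree.SubElement(front, "article-meta")
    title_group = etree.SubElement(meta, "title-group")
    article_title = etree.SubElement(title_group, "article-title")
    article_title.text = m.title
    abstract_section = m.find("Abstract")
    if abstract_section.blocks:
        abstract = etree.SubElement(meta, "abstract")
        for block in abstract_section.blocks:
            p = etree.SubElement(abstract, "p")
            p.text = block

    body = etree.SubElement(article, "body")
    for section in m.sections:
        body.append(_jats_sec(section))

    back = etree.SubElement(article, "back")
    if m.supplementary is not None:
        supp = etree.SubElement(back, "supplementary-material", {"id": "S1"})
        label = etree.SubElement(supp, "label")
        label.text = "MIxS checklist (CSV)"
        caption = etree.SubElement(supp, "caption")
        p = etree.SubElement(caption, "p")
        p.text = (
            f"Narrow-format MIxS checklist table, {len(m.supplementary)} rows."
        )
        media = etree.SubElement(
            supp, "media", {f"{{{XLINK_NS}}}href": supplementary_filename(m)}
        )
        media.set("mimetype", "text")
        media.set("mime-subtype", "csv")

    text = etree.tostring(
        article, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")
    return JatsDocument(xml_text=text)


def _html_section(section: Section, depth: int) -> etree._Element:
    div = etree.Element("section")
    heading = etree.SubElement(div, f"h{min(depth + 2, 6)}")
    heading.text = section.spec.title
    for block in section.blocks:
        p = etree.SubElement(div, "p")
        p.text = block
    for child in section.children:
        div.append(_html_section(child, depth + 1))
    return div


def _html_checklist_table(m: Manuscript) -> etree._Element:
    table = etree.Element("table")
    thead = etree.SubElement(table, "thead")
    tr = etree.SubElement(thead, "tr")
    for column in HEADER:
        th = etree.SubElement(tr, "th")
        th.text = column
    tbody = etree.SubElement(table, "tbody")
    for row in m.supplementary.rows:  # type: ignore[union-attr]
        tr = etree.SubElement(tbody, "tr")
        for value in (row.biosample_accession, row.property_class, row.value, row.unit):
            td = etree.SubElement(tr, "td")
            td.text = value
    return table


def render_html(m: Manuscript) -> str:
    """Render a manuscript to standalone HTML.

    One heading per section, nested by hierarchy level; the supplementary
    checklist (when present) is shown as a table inside the Supplementary
    material section.
    """
    html = etree.Element("html", {"lang": "en"})
    head = etree.SubElement(html, "head")
    etree.SubElement(head, "meta", {"charset": "utf-8"})
    title = etree.SubElement(head, "title")
    title.text = m.title
    body = etree.SubElement(html, "body")
    h1 = etree.SubElement(body, "h1")
    h1.text = m.title
    for section in m.sections:
        rendered = _html_section(section, 0)
        if section.spec.title == "Supplementary material" and m.supplementary:
            rendered.append(_html_checklist_table(m))
        body.append(rendered)
    return etree.tostring(
        html, method="html", doctype="<!DOCTYPE html>", pretty_print=True,
        encoding="unicode",
    )
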