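"""Manuscript assembly: template registry, auto-fill, validation, re-import."""

import copy

import pytest
from lxml import etree

from omicspaper.assembler import (
    PLACEHOLDER_MARKER,
    build_manuscript,
    reimport_biosamples,
    section_registry,
    validate,
)
from omicspaper.fixtures import FixtureSpec, generate, write_fixture_dir
from omicspaper.parsers import (
    parse_arrayexpress_protocols,
    parse_biosample,
    parse_experiment,
    parse_sample,
    parse_study,
)
from omicspaper.renderers import render_jats
from omicspaper.transport import DocKind, FixtureBackend

AUTO_SECTIONS = {
    ("Abstract",),
    ("Methods", "Sampling"),
    ("Methods", "Sample processing", "Technologies used"),
    ("Data resources",),
    ("Supplementary material",),
}
MANDATORY_SECTIONS = {"Methods", "Data resources"}


def _manuscript_from(bundle):
    truth = bundle.truth
    return build_manuscript(
        study=truth.study,
        experiments=list(truth.experiments),
        samples=list(truth.samples),
        protocols=list(truth.protocols),
        biosamples=list(truth.biosamples),
    )


@pytest.fixture()
def manuscript(demo_bundle):
    return _manuscript_from(demo_bundle)


# ---------------------------------------------------------------- registry

def test_registry_auto_and_mandatory_sets():
    specs = section_registry()
    paths = {}
    for spec in specs:
        # reconstruct path for the flat view
        chain = [spec.title]
        parent = spec.parent
        by_title = {s.title: s for s in specs}
        while parent is not None:
            chain.append(parent)
            parent = by_title[parent].parent
        paths[tuple(reversed(chain))] = spec
    assert {p for p, s in paths.items() if s.auto_fillable} == AUTO_SECTIONS
    assert {s.title for s in specs if s.mandatory} == MANDATORY_SECTIONS


def test_registry_hierarchy_titles():
    titles = [s.title for s in section_registry()]
    assert titles[0] == "Abstract"
    assert titles[-1] == "Supplementary material"
    assert titles.count("Technologies used") == 2
    for required in ("Introduction", "Methods", "Sampling", "Sample processing",
                     "Data processing", "Biodiversity profile", "Target",
                     "Taxonomic range", "Functional range", "Traits",
                     "Data resources", "Data statistics",
                     "Caveats and limitations", "Usage rights"):
        assert required in titles


# ---------------------------------------------------------------- build

def test_full_build_auto_fills_exactly_the_template_auto_set(manuscript):
    filled = set()

    def walk(sections, path):
        for s in sections:
            p = (*path, s.spec.title)
            if s.spec.auto_fillable and s.blocks:
                assert s.provenance == "auto"
                filled.add(p)
            walk(s.children, p)

    walk(manuscript.sections, ())
    assert filled == AUTO_SECTIONS


def test_abstract_content_is_study_abstract(manuscript, demo_bundle):
    assert manuscript.find("Abstract").blocks == [demo_bundle.truth.study.abstract]


def test_placeholder_sections_carry_guidance_and_marker(manuscript):
    target = manuscript.find("Biodiversity profile", "Target")
    assert target.provenance == "placeholder"
    assert len(target.blocks) == 1
    assert PLACEHOLDER_MARKER in target.blocks[0]


def test_section_order_matches_registry(manuscript):
    rendered = [s.spec.title for s in manuscript.iter_sections()]
    assert rendered == [s.title for s in section_registry()]


def test_data_resources_order_fastq_then_accessions(manuscript, demo_bundle):
    blocks = manuscript.find("Data resources").blocks
    assert blocks[0].startswith("FASTQ files: ")
    assert demo_bundle.truth.study.fastq_link in blocks[0]
    assert blocks[1].startswith("Experiment accessions: ERX000001, ERX000002")
    assert blocks[2].startswith("Sample accessions: ERS000001")


def test_duplicate_library_strategies_deduplicated(demo_bundle):
    truth = demo_bundle.truth
    doubled = list(truth.experiments) * 2
    m = build_manuscript(truth.study, doubled, [], [], [])
    blocks = m.find("Methods", "Sample processing", "Technologies used").blocks
    strategy_lines = [b for b in blocks if b.startswith("Library strategy: ")]
    # set-union oracle over the experiment fields
    assert len(strategy_lines) == len({e.library_strategy for e in doubled})


def test_study_only_build(demo_bundle):
    study = demo_bundle.truth.study
    m = build_manuscript(study)
    assert m.find("Abstract").blocks == [study.abstract]
    assert m.find("Methods", "Sampling").blocks == []
    assert m.supplementary is None
    assert "no-biosamples" in m.warnings
    assert "empty-source:Sampling" in m.warnings


def test_provenance_log_names_documents_and_expressions(manuscript, demo_bundle):
    """Every auto-filled section has log entries pointing at real fetched
    documents and registry expressions."""
    from omicspaper.parsers import XPATH_REGISTRY

    assert manuscript.provenance_log
    real_docs = {d.name for d in demo_bundle.documents} | {"arrayexpress_protocol"}
    section_ids = {s.spec.section_id for s in manuscript.iter_sections()}
    for section_id, source_doc, expression in manuscript.provenance_log:
        assert section_id in section_ids
        assert source_doc in real_docs
        assert expression in XPATH_REGISTRY.values()
    logged_sections = {entry[0] for entry in manuscript.provenance_log}
    assert logged_sections == {"Abstract", "Sampling", "Technologies used",
                               "Data resources", "Supplementary material"}


def test_supplementary_present_iff_biosamples(demo_bundle):
    truth = demo_bundle.truth
    with_bs = _manuscript_from(demo_bundle)
    assert with_bs.supplementary is not None
    assert len(with_bs.supplementary) == sum(
        len(b.properties) for b in truth.biosamples
    )
    without = build_manuscript(truth.study, truth.experiments, truth.samples,
                               truth.protocols, [])
    assert without.supplementary is None


def test_supplementary_cannot_be_set_directly(manuscript):
    with pytest.raises(AttributeError):
        manuscript.supplementary = None


# ---------------------------------------------------------------- validate

def test_full_manuscript_validates_clean(manuscript):
    assert validate(manuscript) == []


def test_emptying_data_resources_yields_one_violation(manuscript):
    m = copy.deepcopy(manuscript)
    m.find("Data resources").blocks = []
    violations = validate(m)
    assert [v.section_id for v in violations] == ["Data resources"]


def test_emptying_methods_subtree_yields_one_violation(manuscript):
    m = copy.deepcopy(manuscript)
    for section in m.find("Methods").iter():
        if section.provenance == "auto":
            section.blocks = []
    violations = validate(m)
    assert [v.section_id for v in violations] == ["Methods"]


def test_non_mandatory_sections_never_flagged(demo_bundle):
    # a bare study without even a FASTQ link misses Abstract content and the
    # supplementary too, but only the mandatory pair is reported
    import dataclasses

    study = dataclasses.replace(demo_bundle.truth.study, fastq_link=None)
    m = build_manuscript(study)
    assert {v.section_id for v in validate(m)} == MANDATORY_SECTIONS


# ---------------------------------------------------------------- re-import

def test_reimport_is_idempotent_on_unchanged_fixtures(tmp_path, demo_bundle):
    write_fixture_dir(demo_bundle, tmp_path)
    backend = FixtureBackend(tmp_path)
    m = _manuscript_from(demo_bundle)
    m2 = reimport_biosamples(m, backend)
    assert m2.supplementary == m.supplementary
    assert render_jats(m2).xml_text == render_jats(m).xml_text


def test_reimport_picks_up_added_property(tmp_path, demo_bundle):
    write_fixture_dir(demo_bundle, tmp_path)
    backend = FixtureBackend(tmp_path)
    m = _manuscript_from(demo_bundle)
    before = render_jats(m).xml_text

    # grow one fixture biosample by one Property
    target = tmp_path / "SAMEA0000001.biosample.xml"
    root = etree.fromstring(target.read_bytes())
    prop = etree.SubElement(root, "Property")
    prop.set("class", "ammonium")
    qualified = etree.SubElement(prop, "QualifiedValue")
    etree.SubElement(qualified, "Value").text = "0.4"
    etree.SubElement(qualified, "Unit").text = "micromole per liter"
    target.write_bytes(etree.tostring(root, xml_declaration=True,
                                      encoding="UTF-8", pretty_print=True))

    m2 = reimport_biosamples(m, backend)
    assert len(m2.supplementary) == len(m.supplementary) + 1
    # diff oracle over rendered sections: only the supplementary arm changed
    def secs(xml_text):
        article = etree.fromstring(xml_text.encode())
        return {
            sec.get("sec-type"): etree.tostring(sec)
            for sec in article.iter("sec")
        }
    before_secs, after_secs = secs(before), secs(render_jats(m2).xml_text)
    assert set(before_secs) == set(after_secs)
    changed = {k for k in before_secs if before_secs[k] != after_secs[k]}
    assert changed <= {"Supplementary material"}


def test_reimport_missing_biosample_keeps_stale_rows(tmp_path, demo_bundle):
    write_fixture_dir(demo_bundle, tmp_path)
    backend = FixtureBackend(tmp_path)
    m = _manuscript_from(demo_bundle)
    (tmp_path / "SAMEA0000002.biosample.xml").unlink()
    m2 = reimport_biosamples(m, backend)
    assert m2.supplementary == m.supplementary
    assert any(w.startswith("reimport-missing-record:SAMEA0000002")
               for w in m2.warnings)


def test_reimport_requires_recorded_biosamples(demo_bundle):
    m = build_manuscript(demo_bundle.truth.study)
    with pytest.raises(ValueError):
        reimport_biosamples(m, backend=None)
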