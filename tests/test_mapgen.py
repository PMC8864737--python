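"""Map loading, SVG rendering, gene extraction, cards and linting."""

import dataclasses
import glob
import os

import pytest
import yaml
from lxml import etree

from wormpaths.errors import CrossRefError, SchemaError
from wormpaths.mapgen import (
    MapEdge,
    MapNode,
    MetaboliteCard,
    StyleConfig,
    build_metabolite_card,
    extract_map_genes,
    lint_map,
    load_map_definition,
    render_map,
    write_lint_report,
)
from wormpaths.model import Gene, GeneRule, MetabolicModel, Metabolite, NO_STRUCTURE, Reaction
from wormpaths.model import genes_of_reaction

from conftest import build_terminal_mapdef, build_terminal_model, _rxn

SVG_NS = "{http://www.w3.org/2000/svg}"


@pytest.fixture(scope="module")
def map_files(toy_dir):
    return sorted(glob.glob(os.path.join(toy_dir, "maps", "*.yaml")))


def _gene_union(mapdef, model):
    union = set()
    for e in mapdef.edges:
        if e.reaction in model.reactions:
            union |= genes_of_reaction(model, e.reaction)
    return union


# ---------------------------------------------------------------------------
# Loading


def test_load_fixture_maps(map_files, toy_model):
    for f in map_files:
        mapdef = load_map_definition(f, model=toy_model, strict=True)
        assert mapdef.nodes and mapdef.edges
        assert not mapdef.pending_issues


def test_unresolved_ref_strict_vs_lenient(map_files, toy_model, tmp_path):
    doc = yaml.safe_load(open(map_files[0]))
    doc["nodes"].append({"met": "ghost[c]", "x": 1, "y": 1})
    bad = tmp_path / "bad.yaml"
    bad.write_text(yaml.safe_dump(doc))
    with pytest.raises(CrossRefError):
        load_map_definition(bad, model=toy_model, strict=True)
    lenient = load_map_definition(bad, model=toy_model, strict=False)
    assert ("MET_UNRESOLVED", "ghost[c]") in lenient.pending_issues


def test_malformed_map_document(tmp_path):
    p = tmp_path / "broken.yaml"
    p.write_text("nodes: [")
    with pytest.raises(SchemaError):
        load_map_definition(p)
    p2 = tmp_path / "nomap.yaml"
    p2.write_text("nodes: []\n")
    with pytest.raises(SchemaError):
        load_map_definition(p2)


def test_node_outside_canvas_rejected(map_files, tmp_path):
    doc = yaml.safe_load(open(map_files[0]))
    doc["nodes"][0]["x"] = doc["map"]["canvas"]["width"] + 100
    p = tmp_path / "off.yaml"
    p.write_text(yaml.safe_dump(doc))
    with pytest.raises(SchemaError):
        load_map_definition(p)


# ---------------------------------------------------------------------------
# Rendering


def test_render_roundtrip_on_all_fixture_maps(map_files, toy_model, toy_aset, tmp_path):
    """Genes extracted from the rendered SVG equal the map's gene union."""
    for f in map_files:
        mapdef = load_map_definition(f, model=toy_model)
        svg = render_map(mapdef, toy_model, toy_aset)
        out = tmp_path / (os.path.basename(f) + ".svg")
        out.write_bytes(svg)
        assert extract_map_genes(out) == _gene_union(mapdef, toy_model)


def test_rendered_svg_wellformed_with_one_legend(map_files, toy_model, toy_aset):
    mapdef = load_map_definition(map_files[0], model=toy_model)
    root = etree.fromstring(render_map(mapdef, toy_model, toy_aset))
    legends = [g for g in root.iter(SVG_NS + "g") if g.get("class") == "wp-legend"]
    assert len(legends) == 1


def test_render_deterministic(map_files, toy_model, toy_aset):
    mapdef = load_map_definition(map_files[0], model=toy_model)
    assert render_map(mapdef, toy_model, toy_aset) == render_map(mapdef, toy_model, toy_aset)


def test_edge_colors_by_reaction_type(terminal_model):
    model, aset = terminal_model
    mapdef = build_terminal_mapdef()
    mapdef.nodes.append(MapNode("hisd[e]", 60, 220))
    mapdef.edges.append(MapEdge("T1", ((200, 164), (60, 224))))
    style = StyleConfig()
    root = etree.fromstring(render_map(mapdef, model, aset))
    lines = list(root.iter(SVG_NS + "polyline"))
    transport = [l for l in lines if l.get("stroke") == style.color_transport_edge]
    enzymatic = [l for l in lines if l.get("stroke") == style.color_enzymatic_edge]
    assert len(transport) == 1 and len(enzymatic) == 4


def test_or_rule_rendered_as_single_label(tmp_path):
    genes = [Gene(g) for g in ("pck-1", "pck-2", "pck-3")]
    mets = [Metabolite("pep", "c"), Metabolite("oaa", "c")]
    rxn = _rxn("R1", ["pep[c]"], ["oaa[c]"], rule=[["pck-1"], ["pck-2"], ["pck-3"]])
    model = MetabolicModel(genes, mets, [rxn])
    from wormpaths.annotation import AnnotationRecord, AnnotationSet
    aset = AnnotationSet([AnnotationRecord(g.id, "carbohydrates", "glycolysis",
                                           "glycolysis", "glycolysis") for g in genes])
    from wormpaths.mapgen import MapDefinition
    mapdef = MapDefinition("m", "t", 4, "glycolysis", 400, 300,
                           nodes=[MapNode("pep[c]", 50, 50), MapNode("oaa[c]", 200, 50)],
                           edges=[MapEdge("R1", ((50, 54), (200, 54)))])
    root = etree.fromstring(render_map(mapdef, model, aset))
    labels = [t.text for t in root.iter(SVG_NS + "text")
              if (t.get("class") or "").startswith("wp-gene")]
    assert labels == ["pck-1|pck-2|pck-3"]
    out = tmp_path / "m.svg"
    out.write_bytes(render_map(mapdef, model, aset))
    assert extract_map_genes(out) == {"pck-1", "pck-2", "pck-3"}


def test_and_label_split_on_extraction(tmp_path):
    svg = (
        '<svg xmlns="http://www.w3.org/2000/svg">'
        '<text class="wp-gene">pdha-1&amp;pdhb-1</text>'
        '<text class="wp-met">pyr</text></svg>'
    )
    p = tmp_path / "x.svg"
    p.write_text(svg)
    assert extract_map_genes(p) == {"pdha-1", "pdhb-1"}


def test_extract_requires_xml(tmp_path):
    p = tmp_path / "bad.svg"
    p.write_text("<svg><unclosed>")
    with pytest.raises(SchemaError):
        extract_map_genes(p)
    empty = tmp_path / "empty.svg"
    empty.write_text('<svg xmlns="http://www.w3.org/2000/svg"><text class="wp-met">x</text></svg>')
    assert extract_map_genes(empty) == set()


def test_style_validates_colors():
    with pytest.raises(SchemaError):
        StyleConfig(color_gene_label="blue")


# ---------------------------------------------------------------------------
# Metabolite cards


def test_card_with_image(tmp_path):
    img = tmp_path / "g6p-B.png"
    img.write_bytes(b"png")
    met = Metabolite("g6p-B", "c", name="beta-D-glucose 6-phosphate",
                     formula="C6H11O9P", structure_ref="g6p-B.png")
    card, issue = build_metabolite_card(met, image_dir=tmp_path)
    assert card.name == "beta-D-glucose 6-phosphate"
    assert card.structure == "g6p-B.png" and issue is None


def test_card_placeholder_when_no_structure():
    met = Metabolite("mystery", "c", name="unknown protein", structure_ref=NO_STRUCTURE)
    card, issue = build_metabolite_card(met)
    assert card.structure == "Structure not available" and issue is None


def test_card_missing_image_warns(tmp_path):
    met = Metabolite("m", "c", name="x", structure_ref="nope.png")
    card, issue = build_metabolite_card(met, image_dir=tmp_path)
    assert card.structure == MetaboliteCard.PLACEHOLDER
    assert issue is not None and issue.severity == "WARNING"


def test_card_empty_formula_ok():
    card, _ = build_metabolite_card(Metabolite("m", "c", name="x", formula=""))
    assert card.formula == ""


# ---------------------------------------------------------------------------
# Linting


def test_clean_fixture_maps_lint_empty(map_files, toy_model, toy_aset):
    for f in map_files:
        mapdef = load_map_definition(f, model=toy_model)
        assert lint_map(mapdef, toy_model, toy_aset).issues == []


def test_clean_terminal_map_lints_empty(terminal_model, terminal_mapdef):
    model, aset = terminal_model
    assert lint_map(terminal_mapdef, model, aset).issues == []


def _mutations():
    """Eight planted mutations, each yielding exactly one issue code."""

    def drop_gene_from_annotations(model, aset, mapdef):
        from wormpaths.annotation import AnnotationSet
        return model, AnnotationSet([r for r in aset.records if r.gene_id != "gv-2"]), mapdef

    def move_gene_to_other_category(model, aset, mapdef):
        from wormpaths.annotation import AnnotationRecord, AnnotationSet
        from conftest import PROP_PATH
        recs = [r for r in aset.records if r.gene_id != "gv-2"]
        recs.append(AnnotationRecord("gv-2", *PROP_PATH))
        return model, AnnotationSet(recs), mapdef

    def unknown_metabolite_node(model, aset, mapdef):
        mapdef.nodes.append(MapNode("ghost[c]", 10, 10))
        return model, aset, mapdef

    def unknown_reaction_edge(model, aset, mapdef):
        mapdef.edges.append(MapEdge("R999", ((1, 1), (2, 2))))
        return model, aset, mapdef

    def unparseable_rule(model, aset, mapdef):
        rxns = [r for r in model.reactions.values() if r.id != "R2"]
        broken = dataclasses.replace(model.reactions["R2"], rule=None, rule_raw="gv-2||x")
        rxns.append(broken)
        return (MetabolicModel(list(model.genes.values()),
                               list(model.metabolites.values()), rxns),
                aset, mapdef)

    def missing_pathway_box(model, aset, mapdef):
        mapdef.boxes = [b for b in mapdef.boxes if b.node != "ppcoa[c]"]
        return model, aset, mapdef

    def orphan_node(model, aset, mapdef):
        mapdef.nodes.append(MapNode("mmcoa[c]", 10, 10))
        return model, aset, mapdef

    def duplicate_node(model, aset, mapdef):
        mapdef.nodes.append(MapNode("valx[c]", 60, 60))
        return model, aset, mapdef

    return [
        (drop_gene_from_annotations, "GENE_NOT_IN_ANNOTATIONS"),
        (move_gene_to_other_category, "GENE_LEVEL_MISMATCH"),
        (unknown_metabolite_node, "MET_UNRESOLVED"),
        (unknown_reaction_edge, "REACTION_UNRESOLVED"),
        (unparseable_rule, "RULE_PARSE_ERROR"),
        (missing_pathway_box, "TERMINAL_RULE_VIOLATION"),
        (orphan_node, "ORPHAN_NODE"),
        (duplicate_node, "DUP_NODE"),
    ]


@pytest.mark.parametrize("mutate, code", _mutations(), ids=[c for _, c in _mutations()])
def test_each_planted_mutation_yields_its_code(mutate, code):
    model, aset = build_terminal_model()
    mapdef = build_terminal_mapdef()
    model, aset, mapdef = mutate(model, aset, mapdef)
    report = lint_map(mapdef, model, aset)
    assert report.codes() == [code]


def test_lint_report_tsv(terminal_model, tmp_path):
    model, aset = terminal_model
    mapdef = build_terminal_mapdef()
    mapdef.nodes.append(MapNode("mmcoa[c]", 10, 10))
    report = lint_map(mapdef, model, aset)
    out = tmp_path / "lint.tsv"
    write_lint_report(report, out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == ["severity", "code", "map", "subject", "message"]
    assert len(lines) == 1 + len(report.issues)
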