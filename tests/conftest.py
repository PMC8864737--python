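import pytest

from wormpaths.annotation import AnnotationRecord, AnnotationSet, load_annotations
from wormpaths.fixtures import ToyModelSpec, generate_toy_model
from wormpaths.mapgen import MapBox, MapDefinition, MapEdge, MapNode
from wormpaths.model import Gene, GeneRule, MetabolicModel, Metabolite, Reaction, load_model


@pytest.fixture(scope="session")
def toy_spec():
    return ToyModelSpec(seed=3, planted_enriched={
        "category_size": 10, "k_in_list": 10, "n_background": 10})


@pytest.fixture(scope="session")
def toy_dir(toy_spec, tmp_path_factory):
    d = tmp_path_factory.mktemp("toyset")
    generate_toy_model(toy_spec, d)
    return d


@pytest.fixture(scope="session")
def toy_manifest(toy_dir):
    import json
    with open(toy_dir / "manifest.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def toy_model(toy_dir):
    return load_model(toy_dir / "genes.tsv", toy_dir / "metabolites.tsv",
                      toy_dir / "reactions.tsv")


@pytest.fixture(scope="session")
def toy_aset(toy_dir):
    return load_annotations(toy_dir / "annotations.tsv")


# ---------------------------------------------------------------------------
# Hand-built valine-degradation-style model exercising every terminal
# archetype: a defining substrate, a pathway-box connection, a transportable
# endpoint, an unmapped ("other") endpoint, and a many-pathway hub.

VAL_PATH = ("amino acids", "branched-chain amino acid degradation",
            "valine degradation", "valine degradation")
PROP_PATH = ("lipids", "short-chain fatty acid degradation",
             "propionate degradation", "propionate degradation")


def _rxn(rid, subs, prods, rule=None, rtype="enzymatic", reversible=False, raw=""):
    return Reaction(
        id=rid,
        substrates=tuple((s, 1.0) for s in subs),
        products=tuple((p, 1.0) for p in prods),
        reversible=reversible, rtype=rtype,
        rule=GeneRule(tuple(tuple(c) for c in rule)) if rule else None,
        rule_raw=raw or ("" if rule is None else
                         "|".join("&".join(c) for c in rule)),
    )


def build_terminal_model():
    genes = [Gene(g) for g in ("gv-1", "gv-2", "gv-3", "gv-4", "gp-1",
                               "gh-1", "gh-2", "gh-3", "gh-4", "gh-5")]
    mets = [Metabolite(a, c) for a, c in [
        ("valx", "c"), ("urcan", "c"), ("ppcoa", "c"), ("hisd", "c"), ("hisd", "e"),
        ("deadend", "c"), ("mmcoa", "c"), ("hub", "c"), ("aux1", "c"), ("aux2", "c"),
    ]]
    rxns = [
        _rxn("R1", ["valx[c]"], ["urcan[c]"], rule=[["gv-1"]]),
        _rxn("R2", ["urcan[c]"], ["ppcoa[c]"], rule=[["gv-2"]]),
        _rxn("R3", ["urcan[c]"], ["hisd[c]"], rule=[["gv-3"]]),
        _rxn("R4", ["urcan[c]"], ["deadend[c]"], rule=[["gv-4"]]),
        _rxn("R5", ["ppcoa[c]"], ["mmcoa[c]"], rule=[["gp-1"]]),
        _rxn("T1", ["hisd[c]"], ["hisd[e]"], rtype="transport", reversible=True),
    ]
    # hub[c] takes part in five explicitly assigned pathways
    for i in range(1, 6):
        rxns.append(_rxn(f"H{i}", ["hub[c]"], ["aux1[c]"], rule=[[f"gh-{i}"]]))
    records = [AnnotationRecord(g, *VAL_PATH) for g in ("gv-1", "gv-2", "gv-3", "gv-4")]
    records.append(AnnotationRecord("gp-1", *PROP_PATH))
    for i in range(1, 6):
        records.append(AnnotationRecord(
            f"gh-{i}", "other", f"hub pathway {i}", f"hub pathway {i}", f"hub pathway {i}"))
    return MetabolicModel(genes, mets, rxns), AnnotationSet(records)


def build_terminal_mapdef(with_boxes=True, extra_nodes=(), extra_edges=(),
                          extra_terminals=()):
    nodes = [
        MapNode("valx[c]", 60, 60, terminal=True, main_terminus=True),
        MapNode("urcan[c]", 200, 60),
        MapNode("ppcoa[c]", 340, 60, terminal=True),
        MapNode("hisd[c]", 200, 160, terminal=True),
        MapNode("deadend[c]", 340, 160, terminal=True),
    ]
    for m in extra_terminals:
        nodes.append(MapNode(m, 60, 160, terminal=True))
    nodes.extend(extra_nodes)
    edges = [
        MapEdge("R1", ((60, 64), (200, 64))),
        MapEdge("R2", ((200, 64), (340, 64))),
        MapEdge("R3", ((200, 64), (200, 164))),
        MapEdge("R4", ((200, 64), (340, 164))),
    ]
    edges.extend(extra_edges)
    boxes = []
    if with_boxes:
        boxes = [
            MapBox("pathway", "propionate degradation", 400, 50, node="ppcoa[c]"),
            MapBox("other", None, 400, 150, node="deadend[c]"),
        ]
    return MapDefinition(
        map_id="valine-deg", title="Valine degradation", level=3,
        category="valine degradation", width=560, height=400,
        nodes=nodes, edges=edges, boxes=boxes,
        reaction_pathways={f"H{i}": f"hub pathway {i}" for i in range(1, 6)},
    )


@pytest.fixture()
def terminal_model():
    return build_terminal_model()


@pytest.fixture()
def terminal_mapdef():
    return build_terminal_mapdef()
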