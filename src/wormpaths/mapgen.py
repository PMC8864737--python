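"""Standardized SVG pathway maps: declarative definition, renderer, linter.

A map definition is a YAML document that places metabolite nodes at fixed
pixel coordinates (maps are hand-laid-out; the renderer honors the given
geometry), routes reaction edges as polylines, and declares pathway/"other"
boxes and compartment regions.  The renderer emits deterministic SVG 1.1
following the house conventions: black enzymatic edges, green transport
edges, blue gene labels with ``|`` between OR alternatives and ``&`` within
AND chains, orange co-reactant labels, a grayscale pathway-count square and
transport circles per metabolite, hoverable metabolite cards as
``<title>`` metadata, and one legend group appended to every map.

Structural class attributes (``wp-gene``, ``wp-met``, ``wp-coreactant``,
``wp-legend``) make extraction and styling independent of colors, which is
what the linter's gene extraction relies on.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import yaml
from lxml import etree

from .annotation import AnnotationSet
from .connectivity import (
    DEFAULT_BOX_THRESHOLD,
    TerminalKind,
    annotate_metabolite,
    classify_terminal,
    grayscale_bin,
    GRAYSCALE_BINS,
)
from .errors import CrossRefError, SchemaError, WormPathsError
from .model import NO_STRUCTURE, MetabolicModel, Metabolite

SVG_NS = "http://www.w3.org/2000/svg"
XLINK_NS = "http://www.w3.org/1999/xlink"
NSMAP = {None: SVG_NS, "xlink": XLINK_NS}

_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")


@dataclass(frozen=True)
class StyleConfig:
    """Colors and typography of the standardized map template."""

    color_enzymatic_edge: str = "#000000"
    color_transport_edge: str = "#2e8b57"
    color_gene_label: str = "#1f4fd8"
    color_coreactant: str = "#e07b00"
    color_circle_ce: str = "#d62728"   # cytosol <-> extracellular circle
    color_circle_mc: str = "#9467bd"   # mitochondria <-> cytosol circle
    grayscale_bins: tuple[str, ...] = GRAYSCALE_BINS
    font_family: str = "Helvetica, Arial, sans-serif"
    font_size: float = 12.0
    link_template: str = "#met-{met}"  # hyperlink target per metabolite

    def __post_init__(self):
        for name in ("color_enzymatic_edge", "color_transport_edge", "color_gene_label",
                     "color_coreactant", "color_circle_ce", "color_circle_mc"):
            v = getattr(self, name)
            if not _HEX_RE.match(v):
                raise SchemaError(f"style color {name} must be #rrggbb hex, got {v!r}")
        for v in self.grayscale_bins:
            if not _HEX_RE.match(v):
                raise SchemaError(f"grayscale bin color must be #rrggbb hex, got {v!r}")


@dataclass(frozen=True)
class MapNode:
    met: str  # full ref "abbr[comp]"
    x: float
    y: float
    terminal: bool = False
    main_terminus: bool = False

    @property
    def abbr(self) -> str:
        return self.met.split("[", 1)[0]


@dataclass(frozen=True)
class MapEdge:
    reaction: str
    waypoints: tuple[tuple[float, float], ...]
    label_anchor: tuple[float, float] | None = None


@dataclass(frozen=True)
class MapBox:
    kind: str  # pathway | other
    target: str | None  # pathway name, None for "other"
    x: float
    y: float
    node: str | None = None  # terminal metabolite this box belongs to


@dataclass(frozen=True)
class MapRegion:
    label: str
    x: float
    y: float
    width: float
    height: float


@dataclass
class MapDefinition:
    map_id: str
    title: str
    level: int
    category: str
    width: float
    height: float
    nodes: list[MapNode] = field(default_factory=list)
    edges: list[MapEdge] = field(default_factory=list)
    boxes: list[MapBox] = field(default_factory=list)
    regions: list[MapRegion] = field(default_factory=list)
    reaction_pathways: dict[str, str] = field(default_factory=dict)
    pending_issues: list = field(default_factory=list)  # lenient-load deferred problems

    def node_for(self, met: str) -> MapNode | None:
        for n in self.nodes:
            if n.met == met:
                return n
        return None

    def terminals(self) -> list[MapNode]:
        return [n for n in self.nodes if n.terminal]

    def boxes_for(self, met: str) -> list[MapBox]:
        return [b for b in self.boxes if b.node == met]

    def reaction_pathways_table(self) -> dict[str, str]:
        return dict(self.reaction_pathways)


@dataclass(frozen=True)
class MetaboliteCard:
    met: str
    name: str
    formula: str
    structure: str  # image ref, or the exact placeholder text

    PLACEHOLDER = "Structure not available"


@dataclass(frozen=True)
class LintIssue:
    severity: str  # ERROR | WARNING
    code: str
    map_id: str
    subject: str
    message: str


@dataclass
class LintReport:
    issues: list[LintIssue] = field(default_factory=list)

    def add(self, severity, code, map_id, subject, message):
        self.issues.append(LintIssue(severity, code, map_id, subject, message))

    @property
    def ok(self) -> bool:
        return not self.issues

    def errors(self) -> list[LintIssue]:
        return [i for i in self.issues if i.severity == "ERROR"]

    def codes(self) -> list[str]:
        return [i.code for i in self.issues]


# ---------------------------------------------------------------------------
# Map definition loading

def load_map_definition(path, model: MetabolicModel | None = None, strict: bool = True) -> MapDefinition:
    """Load and validate a YAML map definition.

    With a model supplied, metabolite/reaction references are resolved; in
    strict mode an unresolved reference raises, in lenient mode it is
    recorded on ``pending_issues`` for the linter.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaError(f"{path}: malformed map document: {exc}") from exc
    if not isinstance(doc, dict) or "map" not in doc:
        raise SchemaError(f"{path}: map document must have a top-level 'map' key")
    meta = doc["map"]
    for key in ("id", "title", "level", "category", "canvas"):
        if key not in meta:
            raise SchemaError(f"{path}: map section missing key {key!r}")
    canvas = meta["canvas"]
    mapdef = MapDefinition(
        map_id=str(meta["id"]),
        title=str(meta["title"]),
        level=int(meta["level"]),
        category=str(meta["category"]),
        width=float(canvas["width"]),
        height=float(canvas["height"]),
    )
    if mapdef.level not in (1, 2, 3, 4):
        raise SchemaError(f"{path}: map level must be 1..4, got {mapdef.level}")
    for nd in doc.get("nodes", []) or []:
        node = MapNode(
            met=str(nd["met"]), x=float(nd["x"]), y=float(nd["y"]),
            terminal=bool(nd.get("terminal", False)),
            main_terminus=bool(nd.get("main_terminus", False)),
        )
        if not (0 <= node.x <= mapdef.width and 0 <= node.y <= mapdef.height):
            raise SchemaError(
                f"{path}: node {node.met!r} at ({node.x}, {node.y}) is outside the canvas"
            )
        mapdef.nodes.append(node)
    for ed in doc.get("edges", []) or []:
        wps = tuple((float(p[0]), float(p[1])) for p in ed.get("waypoints", []))
        if len(wps) < 2:
            raise SchemaError(f"{path}: edge {ed.get('reaction')!r} needs >= 2 waypoints")
        anchor = ed.get("label_anchor")
        mapdef.edges.append(
            MapEdge(
                reaction=str(ed["reaction"]), waypoints=wps,
                label_anchor=(float(anchor[0]), float(anchor[1])) if anchor else None,
            )
        )
    for bx in doc.get("boxes", []) or []:
        kind = str(bx.get("kind", "pathway"))
        if kind not in ("pathway", "other"):
            raise SchemaError(f"{path}: box kind must be pathway or other, got {kind!r}")
        mapdef.boxes.append(
            MapBox(kind=kind, target=bx.get("target"), x=float(bx["x"]), y=float(bx["y"]),
                   node=bx.get("node"))
        )
    for rg in doc.get("regions", []) or []:
        mapdef.regions.append(
            MapRegion(label=str(rg["label"]), x=float(rg["x"]), y=float(rg["y"]),
                      width=float(rg["width"]), height=float(rg["height"]))
        )
    rp = doc.get("reaction_pathways", {}) or {}
    mapdef.reaction_pathways = {str(k): str(v) for k, v in rp.items()}

    if model is not None:
        missing = []
        for n in mapdef.nodes:
            if n.met not in model.metabolites:
                missing.append(("MET_UNRESOLVED", n.met))
        for e in mapdef.edges:
            if e.reaction not in model.reactions:
                missing.append(("REACTION_UNRESOLVED", e.reaction))
        if missing:
            if strict:
                raise CrossRefError(
                    f"{path}: unresolved references: "
                    + ", ".join(f"{c}:{s}" for c, s in missing),
                    missing=[s for _, s in missing],
                )
            mapdef.pending_issues.extend(missing)
    return mapdef


# ---------------------------------------------------------------------------
# Metabolite cards

def build_metabolite_card(met: Metabolite, image_dir=None) -> tuple[MetaboliteCard, LintIssue | None]:
    """Assemble the hover card (name, formula, structure reference).

    When the metabolite declares no structure, or the declared image file is
    missing from ``image_dir``, the card carries the exact placeholder text
    instead; a missing file additionally yields a warning-level lint issue.
    """
    issue = None
    structure = MetaboliteCard.PLACEHOLDER
    if met.structure_ref and met.structure_ref != NO_STRUCTURE:
        candidate = met.structure_ref
        if image_dir is not None:
            candidate = os.path.join(image_dir, met.structure_ref)
        if image_dir is not None and not os.path.exists(candidate):
            issue = LintIssue(
                "WARNING", "STRUCTURE_IMAGE_MISSING", "", met.ref,
                f"structure image {met.structure_ref!r} not found; placeholder used",
            )
        else:
            structure = met.structure_ref
    return MetaboliteCard(met=met.ref, name=met.name, formula=met.formula, structure=structure), issue


# ---------------------------------------------------------------------------
# Rendering

def _el(parent, tag, text=None, **attrs):
    e = etree.SubElement(parent, f"{{{SVG_NS}}}{tag}")
    for k, v in attrs.items():
        e.set(k.replace("__", "-"), str(v))
    if text is not None:
        e.text = text
    return e


def render_map(mapdef: MapDefinition, model: MetabolicModel, aset: AnnotationSet,
               style: StyleConfig | None = None, box_threshold: int = DEFAULT_BOX_THRESHOLD,
               image_dir=None, strict: bool = True) -> bytes:
    """Render a map definition to SVG 1.1 bytes.

    Output is deterministic for fixed inputs: elements follow definition
    order and ids derive from stable tokens, so re-rendering is
    byte-identical.
    """
    style = style or StyleConfig()
    if strict and mapdef.pending_issues:
        raise CrossRefError(
            f"map {mapdef.map_id!r} has unresolved references: "
            + ", ".join(s for _, s in mapdef.pending_issues),
            missing=[s for _, s in mapdef.pending_issues],
        )
    root = etree.Element(f"{{{SVG_NS}}}svg", nsmap=NSMAP)
    root.set("version", "1.1")
    root.set("width", _num(mapdef.width))
    root.set("height", _num(mapdef.height))
    root.set("viewBox", f"0 0 {_num(mapdef.width)} {_num(mapdef.height)}")
    root.set("font-family", style.font_family)
    root.set("font-size", _num(style.font_size))
    _el(root, "title", text=mapdef.title)
    _el(root, "desc", text=f"{mapdef.map_id}: level {mapdef.level} map of {mapdef.category}")

    g_regions = _el(root, "g", **{"class": "wp-regions"})
    for rg in mapdef.regions:
        _el(g_regions, "rect", x=_num(rg.x), y=_num(rg.y), width=_num(rg.width),
            height=_num(rg.height), fill="none", stroke="#bbbbbb",
            **{"stroke-dasharray": "6 3"})
        _el(g_regions, "text", text=rg.label, x=_num(rg.x + 4), y=_num(rg.y + 14),
            fill="#888888", **{"class": "wp-region-label"})

    g_edges = _el(root, "g", **{"class": "wp-edges"})
    for edge in mapdef.edges:
        rxn = model.reactions.get(edge.reaction)
        is_transport = rxn is not None and rxn.rtype == "transport"
        color = style.color_transport_edge if is_transport else style.color_enzymatic_edge
        cls = "wp-edge wp-edge-transport" if is_transport else "wp-edge wp-edge-enzymatic"
        pts = " ".join(f"{_num(x)},{_num(y)}" for x, y in edge.waypoints)
        _el(g_edges, "polyline", points=pts, fill="none", stroke=color,
            **{"stroke-width": "1.5", "class": cls, "id": f"edge-{edge.reaction}"})
        if rxn is not None:
            anchor = edge.label_anchor or _midpoint(edge.waypoints)
            if rxn.rule is not None:
                _el(g_edges, "text", text=str(rxn.rule), x=_num(anchor[0]), y=_num(anchor[1]),
                    fill=style.color_gene_label, **{"class": "wp-gene"})
            elif rxn.rule_raw:  # unparseable rule kept verbatim (lenient load)
                _el(g_edges, "text", text=rxn.rule_raw, x=_num(anchor[0]), y=_num(anchor[1]),
                    fill=style.color_gene_label, **{"class": "wp-gene wp-gene-unparsed"})
            if rxn.co_reactants:
                mid = _midpoint(edge.waypoints)
                label = ", ".join(m.split("[", 1)[0] for m in rxn.co_reactants)
                _el(g_edges, "text", text=label, x=_num(mid[0]), y=_num(mid[1] + 12),
                    fill=style.color_coreactant, **{"class": "wp-coreactant"})

    g_nodes = _el(root, "g", **{"class": "wp-nodes"})
    for node in mapdef.nodes:
        met = model.metabolites.get(node.met)
        a = etree.SubElement(g_nodes, f"{{{SVG_NS}}}a")
        a.set(f"{{{XLINK_NS}}}href", style.link_template.format(met=node.abbr))
        txt = _el(a, "text", text=node.abbr, x=_num(node.x), y=_num(node.y),
                  **{"class": "wp-met", "id": f"met-{node.met}", "text-anchor": "middle"})
        if met is not None:
            card, _ = build_metabolite_card(met, image_dir=image_dir)
            _el(a, "title", text=f"{card.name} | {card.formula} | {card.structure}")
            ann = annotate_metabolite(model, aset, node.met, level=mapdef.level,
                                      explicit=mapdef.reaction_pathways_table())
            if ann.pathway_count > 0:
                _el(g_nodes, "rect", x=_num(node.x + 6), y=_num(node.y - 16), width="8",
                    height="8", fill=grayscale_bin(ann.pathway_count),
                    **{"class": "wp-count-square"})
            cx = node.x - 10
            for tclass in sorted(ann.transport_classes, key=lambda t: t.value):
                color = style.color_circle_ce if tclass.value == "C_E" else style.color_circle_mc
                _el(g_nodes, "circle", cx=_num(cx), cy=_num(node.y - 12), r="4", fill=color,
                    **{"class": f"wp-transport-circle wp-transport-{tclass.value}"})
                cx -= 10

    g_boxes = _el(root, "g", **{"class": "wp-boxes"})
    for box in mapdef.boxes:
        label = box.target if box.kind == "pathway" else "other"
        cls = f"wp-box wp-box-{box.kind}"
        _el(g_boxes, "rect", x=_num(box.x), y=_num(box.y), width="120", height="22",
            rx="4", fill="#f2f2f2", stroke="#333333", **{"class": cls})
        _el(g_boxes, "text", text=label, x=_num(box.x + 6), y=_num(box.y + 15),
            **{"class": "wp-box-label"})

    _render_legend(root, style, mapdef)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _render_legend(root, style: StyleConfig, mapdef: MapDefinition):
    """The key appended to every map: edge colors, pathway-count squares,
    transport circles."""
    g = _el(root, "g", **{"class": "wp-legend"})
    x = 10.0
    y = mapdef.height - 78
    _el(g, "rect", x=_num(x - 4), y=_num(y - 14), width="250", height="86",
        fill="#ffffff", stroke="#999999")
    _el(g, "text", text="Key", x=_num(x), y=_num(y), **{"font-weight": "bold"})
    _el(g, "line", x1=_num(x), y1=_num(y + 10), x2=_num(x + 24), y2=_num(y + 10),
        stroke=style.color_enzymatic_edge, **{"stroke-width": "1.5"})
    _el(g, "text", text="enzymatic reaction", x=_num(x + 30), y=_num(y + 14))
    _el(g, "line", x1=_num(x), y1=_num(y + 24), x2=_num(x + 24), y2=_num(y + 24),
        stroke=style.color_transport_edge, **{"stroke-width": "1.5"})
    _el(g, "text", text="transport reaction", x=_num(x + 30), y=_num(y + 28))
    for i, fill in enumerate(style.grayscale_bins):
        _el(g, "rect", x=_num(x + i * 12), y=_num(y + 34), width="8", height="8", fill=fill)
    _el(g, "text", text="pathways per metabolite (1, 2, 3, ≥4)",
        x=_num(x + 54), y=_num(y + 42))
    _el(g, "circle", cx=_num(x + 4), cy=_num(y + 54), r="4", fill=style.color_circle_ce)
    _el(g, "text", text="cytosol–extracellular transport", x=_num(x + 14), y=_num(y + 58))
    _el(g, "circle", cx=_num(x + 4), cy=_num(y + 68), r="4", fill=style.color_circle_mc)
    _el(g, "text", text="mitochondria–cytosol transport", x=_num(x + 14), y=_num(y + 72))


def _midpoint(waypoints):
    i = (len(waypoints) - 1) // 2
    (x1, y1), (x2, y2) = waypoints[i], waypoints[i + 1] if i + 1 < len(waypoints) else waypoints[i]
    return ((x1 + x2) / 2, (y1 + y2) / 2)


def _num(v) -> str:
    f = float(v)
    return str(int(f)) if f == int(f) else f"{f:g}"


# ---------------------------------------------------------------------------
# Gene extraction and linting

def extract_map_genes(svg_path) -> set[str]:
    """Extract the set of gene ids from a rendered map's gene-labeled text
    elements, splitting OR (``|``) and AND (``&``) labels into genes."""
    try:
        tree = etree.parse(str(svg_path))
    except etree.XMLSyntaxError as exc:
        raise SchemaError(f"{svg_path}: not well-formed XML: {exc}") from exc
    genes = set()
    for el in tree.iter(f"{{{SVG_NS}}}text"):
        cls = el.get("class", "")
        if "wp-gene" in cls.split():
            for tok in re.split(r"[|&]", el.text or ""):
                tok = tok.strip()
                if tok:
                    genes.add(tok)
    return genes


def lint_map(mapdef: MapDefinition, model: MetabolicModel, aset: AnnotationSet,
             box_threshold: int = DEFAULT_BOX_THRESHOLD) -> LintReport:
    """Cross-reference a map against the model and the annotation table.

    Stable issue codes: GENE_NOT_IN_ANNOTATIONS, GENE_LEVEL_MISMATCH,
    MET_UNRESOLVED, REACTION_UNRESOLVED, RULE_PARSE_ERROR,
    TERMINAL_RULE_VIOLATION, ORPHAN_NODE, DUP_NODE.
    """
    rep = LintReport()
    mid = mapdef.map_id

    seen_mets = set()
    for n in mapdef.nodes:
        if n.met in seen_mets:
            rep.add("ERROR", "DUP_NODE", mid, n.met, "metabolite placed more than once")
        seen_mets.add(n.met)
        if n.met not in model.metabolites:
            rep.add("ERROR", "MET_UNRESOLVED", mid, n.met, "metabolite not in model")

    placed = {n.met for n in mapdef.nodes}
    incident: set[str] = set()
    for e in mapdef.edges:
        rxn = model.reactions.get(e.reaction)
        if rxn is None:
            rep.add("ERROR", "REACTION_UNRESOLVED", mid, e.reaction, "reaction not in model")
            continue
        incident |= set(rxn.metabolite_refs()) & placed
        if rxn.rule is None and rxn.rule_raw:
            rep.add("ERROR", "RULE_PARSE_ERROR", mid, e.reaction,
                    f"gene rule {rxn.rule_raw!r} does not parse")
        elif rxn.rule is not None:
            category_genes = (
                aset.genes_in_category(mapdef.level, mapdef.category)
                if mapdef.category in aset.categories_at_level(mapdef.level)
                else set()
            )
            for g in sorted(rxn.rule.genes()):
                if g not in aset.universe:
                    rep.add("ERROR", "GENE_NOT_IN_ANNOTATIONS", mid, g,
                            "gene on map is absent from the annotation table")
                elif g not in category_genes:
                    rep.add("WARNING", "GENE_LEVEL_MISMATCH", mid, g,
                            f"gene not annotated to {mapdef.category!r} at level {mapdef.level}")

    for n in mapdef.nodes:
        if n.met in model.metabolites and n.met not in incident:
            rep.add("WARNING", "ORPHAN_NODE", mid, n.met, "node has no incident edges")

    for n in mapdef.terminals():
        if n.met not in model.metabolites:
            continue
        cls = classify_terminal(model, aset, mapdef, n.met, box_threshold=box_threshold)
        boxes = mapdef.boxes_for(n.met)
        if cls.kind == TerminalKind.PATHWAY_BOXES:
            drawn = {b.target for b in boxes if b.kind == "pathway"}
            missing = set(cls.pathways) - drawn
            if missing:
                rep.add("WARNING", "TERMINAL_RULE_VIOLATION", mid, n.met,
                        "pathway box expected for: " + ", ".join(sorted(missing)))
        elif cls.kind == TerminalKind.OTHER_BOX:
            if not any(b.kind == "other" for b in boxes):
                rep.add("WARNING", "TERMINAL_RULE_VIOLATION", mid, n.met,
                        "'other' box expected (reactions not mapped yet)")
        else:  # MAIN_TERMINUS, TRANSPORT_ENDPOINT, LINK_ONLY draw no boxes
            if boxes:
                rep.add("WARNING", "TERMINAL_RULE_VIOLATION", mid, n.met,
                        f"no box expected for a {cls.kind.value} terminal")
    return rep


def write_lint_report(report: LintReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("severity\tcode\tmap\tsubject\tmessage\n")
        for i in report.issues:
            fh.write(f"{i.severity}\t{i.code}\t{i.map_id}\t{i.subject}\t{i.message}\n")
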