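"""Metabolite connectivity and terminal-metabolite classification.

Pathway maps annotate every metabolite with (i) the number of distinct
pathways its reactions participate in, shown as a grayscale square, and
(ii) its transportability between compartments, shown as colored circles
for the two legend classes: cytosol <-> extracellular (C_E) and
mitochondria <-> cytosol (M_C).  Terminal metabolites — where a map starts
or ends — are classified into the archetypes that drive box drawing: the
pathway's defining substrate/product, a clickable pathway-box connection to
a small number of other pathways, a transportable endpoint, or an "other"
box when the remaining reactions are not mapped yet.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .annotation import AnnotationSet
from .errors import ContractError, UnknownIdError
from .model import MetabolicModel

#: Methods-derived default: draw pathway boxes for up to this many other
#: pathways ("more than two other pathways" suppresses boxes).  Some maps in
#: practice used a looser cutoff of four; the threshold is configurable.
DEFAULT_BOX_THRESHOLD = 2

#: Grayscale fills for the pathway-count square, binned 1 / 2 / 3 / >=4.
GRAYSCALE_BINS = ("#d9d9d9", "#a6a6a6", "#595959", "#000000")


class TransportClass(str, Enum):
    C_E = "C_E"  # cytosol <-> extracellular
    M_C = "M_C"  # mitochondria <-> cytosol


class TerminalKind(str, Enum):
    MAIN_TERMINUS = "MAIN_TERMINUS"
    PATHWAY_BOXES = "PATHWAY_BOXES"
    TRANSPORT_ENDPOINT = "TRANSPORT_ENDPOINT"
    OTHER_BOX = "OTHER_BOX"
    LINK_ONLY = "LINK_ONLY"  # too many connected pathways for boxes


@dataclass(frozen=True)
class MetaboliteAnnotation:
    met: str  # full ref "abbr[comp]"
    pathway_count: int
    transport_classes: frozenset[TransportClass]


@dataclass(frozen=True)
class TerminalClassification:
    met: str
    within_map: str
    kind: TerminalKind
    pathways: tuple[str, ...] = ()  # targets when kind is PATHWAY_BOXES


def grayscale_bin(pathway_count: int) -> str:
    """Fill color of the pathway-count square (bins 1, 2, 3, >=4)."""
    if pathway_count <= 0:
        return "#ffffff"
    return GRAYSCALE_BINS[min(pathway_count, 4) - 1]


def reaction_pathways(model: MetabolicModel, aset: AnnotationSet, rid: str,
                      level: int = 4, explicit: dict | None = None) -> set[str]:
    """Pathway names a reaction belongs to at the map level.

    An explicit reaction -> pathway assignment (per-map curation) wins when
    provided; otherwise membership is inferred from the union of the rule
    genes' annotations at ``level``.  Orphan reactions without an explicit
    assignment belong to no pathway.
    """
    if explicit and rid in explicit:
        v = explicit[rid]
        return set(v) if isinstance(v, (set, list, tuple)) else {v}
    r = model.reactions[rid]
    if r.rule is None:
        return set()
    out = set()
    for g in r.rule.genes():
        for path in aset.pathways_of_gene(g):
            out.add(path[level - 1])
    return out


def metabolite_pathway_count(model: MetabolicModel, aset: AnnotationSet, met: str,
                             level: int = 4, explicit: dict | None = None) -> int:
    """Number of distinct map-level pathways whose reactions involve ``met``.

    ``met`` may be a full ``abbr[comp]`` ref or a bare abbreviation (all
    compartments pooled, matching the map display which shows the bare
    abbreviation).  Transport reactions that only move the metabolite
    between compartments are ignored.
    """
    _check_met(model, met)
    pathways = set()
    for r in model.reactions_of_metabolite(met):
        if r.rtype == "transport":
            continue
        pathways |= reaction_pathways(model, aset, r.id, level=level, explicit=explicit)
    return len(pathways)


def transport_classes(model: MetabolicModel, met_id: str) -> set[TransportClass]:
    """Legend transport classes of a bare abbreviation.

    C_E iff some transport reaction moves it between cytosol and
    extracellular space, M_C iff between mitochondria and cytosol; any other
    compartment pair is ignored for the legend.
    """
    abbr = met_id.split("[", 1)[0]
    model.metabolite_compartments(abbr)  # raises UnknownIdError if absent
    classes = set()
    for r in model.reactions.values():
        if r.rtype != "transport":
            continue
        for a, c1, c2 in model.transported_pairs(r):
            if a != abbr:
                continue
            pair = frozenset((c1, c2))
            if pair == frozenset(("c", "e")):
                classes.add(TransportClass.C_E)
            elif pair == frozenset(("m", "c")):
                classes.add(TransportClass.M_C)
    return classes


def annotate_metabolite(model, aset, met, level: int = 4, explicit=None) -> MetaboliteAnnotation:
    """Bundle pathway count and transport classes for map rendering."""
    return MetaboliteAnnotation(
        met=met,
        pathway_count=metabolite_pathway_count(model, aset, met, level=level, explicit=explicit),
        transport_classes=frozenset(transport_classes(model, met)),
    )


def classify_terminal(model: MetabolicModel, aset: AnnotationSet, mapdef, met: str,
                      box_threshold: int = DEFAULT_BOX_THRESHOLD,
                      explicit: dict | None = None) -> TerminalClassification:
    """Classify a declared terminal metabolite of a map.

    Decision cascade:

    1. the map marks it as the pathway's defining substrate/product ->
       MAIN_TERMINUS;
    2. it connects to 1..box_threshold other pathways -> PATHWAY_BOXES
       listing them;
    3. no other pathway but a legend-class transport exists ->
       TRANSPORT_ENDPOINT;
    4. neither -> OTHER_BOX (its remaining reactions are not mapped yet);
    5. more than box_threshold other pathways -> LINK_ONLY (no boxes, the
       metabolite's own link carries the connectivity).
    """
    node = mapdef.node_for(met)
    if node is None or not node.terminal:
        raise ContractError(f"{met!r} is not a declared terminal node of map {mapdef.map_id!r}")
    if node.main_terminus:
        return TerminalClassification(met, mapdef.map_id, TerminalKind.MAIN_TERMINUS)
    own = mapdef.category
    explicit = explicit if explicit is not None else mapdef.reaction_pathways_table()
    pathways = set()
    for r in model.reactions_of_metabolite(met):
        if r.rtype == "transport":
            continue
        pathways |= reaction_pathways(model, aset, r.id, level=mapdef.level, explicit=explicit)
    others = sorted(pathways - {own})
    if 1 <= len(others) <= box_threshold:
        return TerminalClassification(met, mapdef.map_id, TerminalKind.PATHWAY_BOXES, tuple(others))
    if len(others) == 0:
        if transport_classes(model, met):
            return TerminalClassification(met, mapdef.map_id, TerminalKind.TRANSPORT_ENDPOINT)
        return TerminalClassification(met, mapdef.map_id, TerminalKind.OTHER_BOX)
    return TerminalClassification(met, mapdef.map_id, TerminalKind.LINK_ONLY)


def _check_met(model: MetabolicModel, met: str):
    if "[" in met:
        if met not in model.metabolites:
            raise UnknownIdError(f"unknown metabolite {met!r}")
    else:
        model.metabolite_compartments(met)
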