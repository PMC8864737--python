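"""Deterministic synthetic fixtures with planted ground truth.

Generates a complete input set — model tables, annotation table, map
definitions, PEA gene lists — whose statistical shape emulates the real
annotation universe (by default at reduced size; :meth:`ToyModelSpec.master_shaped`
reproduces the full-scale shape: 1314 genes, 907 metabolites, 2230
reactions, 10/61/79/85 categories per level, ~32% multi-pathway genes, a
62-map inventory).  Every planted truth (per-gene pathway paths,
per-metabolite pathway counts and transport classes, the enriched
category's k and n) is recorded in a JSON manifest so downstream modules
can be checked exactly.  Generation is a pure function of the spec: the
same spec yields byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .errors import DomainError

#: Broad level-1 classes of the metabolic annotation hierarchy.
LEVEL1_NAMES = (
    "amino acids", "carbohydrates", "cofactors and vitamins", "energy", "lipids",
    "nucleotides", "one-carbon cycle", "reactive oxygen species", "other amino acids",
    "other",
)

#: A realistic nested chain planted into master-shaped hierarchies.
CANONICAL_CHAIN = ("lipids", "short-chain fatty acid degradation",
                   "propionate degradation", "propionate shunt")


@dataclass(frozen=True)
class ToyModelSpec:
    seed: int = 0
    n_genes: int = 120
    n_mets: int = 90
    n_reactions: int = 110
    n_categories_per_level: tuple[int, int, int, int] = (4, 8, 12, 16)
    planted_multi_fraction: float = 0.2
    planted_transport: tuple[tuple[str, str], ...] = (("his", "C_E"), ("akg", "M_C"))
    #: optional planted enrichment: {"category_size": n, "k_in_list": k, "n_background": b}
    planted_enriched: dict | None = None
    n_maps: int = 4
    #: gene id planted with exactly four distinct pathway paths (or None)
    four_path_gene: str | None = None
    plant_canonical_chain: bool = False

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_mets <= 0 or self.n_reactions <= 0:
            raise DomainError("counts must be positive")
        if not (0.0 <= self.planted_multi_fraction <= 1.0):
            raise DomainError("planted_multi_fraction must be in [0, 1]")
        c = self.n_categories_per_level
        if len(c) != 4 or any(x <= 0 for x in c) or any(c[i] > c[i + 1] for i in range(3)):
            raise DomainError("n_categories_per_level must be 4 non-decreasing positive counts")
        if self.planted_enriched:
            pe = self.planted_enriched
            if pe.get("k_in_list", 0) > pe.get("category_size", 0):
                raise DomainError("k_in_list cannot exceed the planted category size")

    @classmethod
    def master_shaped(cls, seed: int = 0, planted_enriched: dict | None = None) -> "ToyModelSpec":
        """Full-scale shape of the reference annotation universe."""
        return cls(
            seed=seed, n_genes=1314, n_mets=907, n_reactions=2230,
            n_categories_per_level=(10, 61, 79, 85),
            planted_multi_fraction=0.32,
            planted_transport=tuple(
                [(f"tm{i}", "C_E") for i in range(8)] + [(f"tn{i}", "M_C") for i in range(8)]
            ),
            planted_enriched=planted_enriched,
            n_maps=62, four_path_gene="alh-2", plant_canonical_chain=True,
        )


# ---------------------------------------------------------------------------
# Hierarchy and gene assignment (shared by model and PEA-input generation)

def _build_hierarchy(spec: ToyModelSpec, rng) -> list[tuple[str, str, str, str]]:
    """Build the 4-level category tree; returns the list of leaf paths.

    At each level transition, enough parents are subdivided (two or more
    children each) to reach the target distinct-name count; the rest inherit
    their name downward, reproducing the redundancy of the real table.
    """
    n1, n2, n3, n4 = spec.n_categories_per_level
    level1 = list(LEVEL1_NAMES[:n1])
    for i in range(len(level1), n1):
        level1.append(f"metabolism group {i + 1}")
    paths = [(c,) for c in level1]
    # one path is forced to subdivide at every level so a fully-distinct
    # 4-deep chain always exists (the canonical chain when planting it)
    forced = ("lipids",) if spec.plant_canonical_chain and "lipids" in level1 else (level1[0],)
    for target, tag in ((n2, "pathway"), (n3, "branch"), (n4, "step")):
        paths, forced = _subdivide(paths, target, tag, rng, forced)
    if spec.plant_canonical_chain:
        paths = _plant_chain(paths)
    return paths


def _subdivide(paths, target, tag, rng, forced):
    c = len(paths)
    if target < c:
        raise DomainError("category counts must be non-decreasing across levels")
    s = min(c, target - c)  # parents that subdivide (>= 2 children each)
    n_children = target - c + s
    force_idx = paths.index(forced)
    order = [int(x) for x in rng.permutation(c)]
    if s > 0:
        order.remove(force_idx)
        order = [force_idx] + order
    subdividers = sorted(order[:s])
    counts = {i: 2 for i in subdividers}
    extra = n_children - 2 * s
    for i in range(extra):
        counts[subdividers[int(rng.integers(0, s))]] += 1
    out = []
    for i, p in enumerate(paths):
        name = p[-1]
        if i in counts:
            for j in range(counts[i]):
                out.append((*p, f"{name} {tag} {j + 1}"))
        else:
            out.append((*p, name))
    new_forced = (*forced, f"{forced[-1]} {tag} 1") if force_idx in counts else (*forced, forced[-1])
    return out, new_forced


def _plant_chain(paths):
    """Rename one fully subdivided chain under 'lipids' to the canonical
    short-chain fatty acid degradation -> propionate shunt path."""
    for idx, p in enumerate(paths):
        if p[0] == "lipids" and p[0] != p[1] and p[1] != p[2] and p[2] != p[3]:
            l2_old, l3_old = p[1], p[2]
            renamed = []
            for q in paths:
                q = list(q)
                if q[1] == l2_old:
                    q[1] = CANONICAL_CHAIN[1]
                if q[2] == l3_old:
                    q[2] = CANONICAL_CHAIN[2]
                renamed.append(tuple(q))
            out = []
            for i, q in enumerate(renamed):
                if i == idx:
                    q = (q[0], q[1], q[2], CANONICAL_CHAIN[3])
                out.append(q)
            return out
    return paths


def _gene_names(spec: ToyModelSpec, rng) -> list[str]:
    letters = "abcdefghijklmnopqrstuvwxyz"
    names, seen = [], set()
    if spec.four_path_gene:
        names.append(spec.four_path_gene)
        seen.add(spec.four_path_gene)
    while len(names) < spec.n_genes:
        stem = "".join(letters[i] for i in rng.integers(0, 26, size=3))
        name = f"{stem}-{int(rng.integers(1, 60))}"
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def _assign_genes(spec: ToyModelSpec, rng, leaves, genes):
    """Assign every gene >= 1 leaf path; plant multi-pathway genes and the
    optional enriched category of exact size.  Returns (gene -> list of leaf
    indexes, enriched leaf index or None)."""
    n_leaves = len(leaves)
    if spec.n_genes < n_leaves:
        raise DomainError("need at least one gene per leaf category")
    enriched_leaf = None
    reserved: set[int] = set()
    assignment: dict[str, list[int]] = {g: [] for g in genes}
    pool_genes = list(genes)
    if spec.planted_enriched:
        size = spec.planted_enriched["category_size"]
        if size < 1 or size > spec.n_genes:
            raise DomainError("planted category size infeasible")
        enriched_leaf = 0
        reserved.add(0)
        members = [genes[i] for i in rng.choice(len(genes), size=size, replace=False)]
        for g in members:
            assignment[g].append(0)
        pool_genes = [g for g in genes if g not in set(members)]
    open_leaves = [i for i in range(n_leaves) if i not in reserved]
    # coverage first: one gene per leaf, then the rest at random
    free = [g for g in pool_genes]
    rng.shuffle(free)
    for j, leaf in enumerate(open_leaves):
        if j < len(free):
            assignment[free[j]].append(leaf)
    for g in free[len(open_leaves):]:
        assignment[g].append(int(rng.choice(open_leaves)))
    # multi-pathway planting: extra distinct leaves for a fixed gene count
    n_multi = round(spec.planted_multi_fraction * spec.n_genes)
    multi_candidates = [g for g in free if assignment[g]]
    four = spec.four_path_gene
    if four:
        while len(assignment[four]) < 4:
            cand = int(rng.choice(open_leaves))
            if cand not in assignment[four]:
                assignment[four].append(cand)
    need = n_multi - (1 if four else 0)
    picked = 0
    for g in multi_candidates:
        if picked >= need:
            break
        if g == four or len(assignment[g]) > 1:
            continue
        cand = int(rng.choice(open_leaves))
        if cand != assignment[g][0]:
            assignment[g].append(cand)
            picked += 1
    # genes untouched by any rule above (e.g. enriched members lacking coverage draw)
    for g, leafs in assignment.items():
        if not leafs:
            assignment[g].append(int(rng.choice(open_leaves)))
    return assignment, enriched_leaf


def _universe(spec: ToyModelSpec):
    """Deterministic (leaves, genes, assignment, enriched_leaf) for a spec."""
    rng = np.random.default_rng(spec.seed)
    leaves = _build_hierarchy(spec, rng)
    genes = _gene_names(spec, rng)
    assignment, enriched_leaf = _assign_genes(spec, rng, leaves, genes)
    return leaves, genes, assignment, enriched_leaf


# ---------------------------------------------------------------------------
# Full input-set generation

def generate_toy_model(spec: ToyModelSpec, out_dir) -> dict:
    """Write genes/metabolites/reactions/annotations TSVs, map YAMLs and the
    ground-truth manifest into ``out_dir``; returns the manifest dict."""
    os.makedirs(out_dir, exist_ok=True)
    leaves, genes, assignment, enriched_leaf = _universe(spec)
    rng = np.random.default_rng(spec.seed + 1)

    # ---- metabolites -----------------------------------------------------
    transports = list(spec.planted_transport)
    met_entries: list[tuple[str, str]] = []
    used_abbrs = set()
    for abbr, tclass in transports:
        if abbr in used_abbrs:
            raise DomainError(f"duplicate planted transport metabolite {abbr!r}")
        used_abbrs.add(abbr)
        pair = ("c", "e") if tclass == "C_E" else ("m", "c")
        met_entries.append((abbr, pair[0]))
        met_entries.append((abbr, pair[1]))
    if len(met_entries) > spec.n_mets:
        raise DomainError("n_mets too small for the planted transports")
    letters = "abcdefghijklmnopqrstuvwxyz"
    while len(met_entries) < spec.n_mets:
        abbr = "".join(letters[i] for i in rng.integers(0, 26, size=int(rng.integers(3, 6))))
        if abbr not in used_abbrs:
            used_abbrs.add(abbr)
            met_entries.append((abbr, "c" if rng.random() < 0.8 else "m"))
    free_refs = [f"{a}[{c}]" for a, c in met_entries[2 * len(transports):]]

    # per-leaf metabolite pools (controls planted pathway counts)
    n_leaves = len(leaves)
    pools: list[list[str]] = [[] for _ in range(n_leaves)]
    for i, ref in enumerate(free_refs):
        pools[i % n_leaves].append(ref)
    for p in pools:
        if len(p) < 2:
            raise DomainError("n_mets too small to give every pathway two metabolites")

    # ---- reactions -------------------------------------------------------
    n_transport_rxns = len(transports)
    n_enzymatic = spec.n_reactions - n_transport_rxns
    if n_enzymatic < 2 * n_leaves:
        raise DomainError("n_reactions too small to give every pathway two reactions")
    genes_by_leaf = {i: [] for i in range(n_leaves)}
    for g, leafs in assignment.items():
        for leaf in leafs:
            genes_by_leaf[leaf].append(g)
    rxn_rows, rxn_pathway = [], {}
    for i in range(n_enzymatic):
        leaf = i % n_leaves if i < 2 * n_leaves else int(rng.integers(0, n_leaves))
        pool = pools[leaf]
        k_sub = 1 + int(rng.random() < 0.5 and len(pool) >= 4)
        k_prod = 1 + int(rng.random() < 0.5 and len(pool) >= 4)
        picks = [pool[j] for j in rng.choice(len(pool), size=k_sub + k_prod, replace=False)]
        subs, prods = picks[:k_sub], picks[k_sub:]
        rule = _random_rule(genes_by_leaf[leaf], rng)
        co = subs[1] if k_sub == 2 and rng.random() < 0.3 else ""
        eq_arrow = "<=>" if rng.random() < 0.3 else "->"
        rid = f"R{i + 1:04d}"
        rxn_rows.append({
            "rxn_id": rid,
            "equation": f"{' + '.join(subs)} {eq_arrow} {' + '.join(prods)}",
            "rtype": "enzymatic", "gene_rule": rule, "co_reactants": co,
        })
        rxn_pathway[rid] = leaves[leaf][3]
    for j, (abbr, tclass) in enumerate(transports):
        a, b = (("c", "e") if tclass == "C_E" else ("m", "c"))
        rxn_rows.append({
            "rxn_id": f"T{j + 1:04d}",
            "equation": f"{abbr}[{a}] <=> {abbr}[{b}]",
            "rtype": "transport", "gene_rule": "", "co_reactants": "",
        })

    # ---- write tables ----------------------------------------------------
    _write_tsv(os.path.join(out_dir, "genes.tsv"), ["gene_id", "aliases"],
               [[g, ""] for g in genes])
    _write_tsv(os.path.join(out_dir, "metabolites.tsv"),
               ["met_id", "compartment", "name", "formula", "structure_ref"],
               [[a, c, f"{a} ({c})", "", "NONE"] for a, c in met_entries])
    _write_tsv(os.path.join(out_dir, "reactions.tsv"),
               ["rxn_id", "equation", "rtype", "gene_rule", "co_reactants"],
               [[r["rxn_id"], r["equation"], r["rtype"], r["gene_rule"], r["co_reactants"]]
                for r in rxn_rows])
    ann_rows = []
    for g in genes:
        for leaf in assignment[g]:
            l1, l2, l3, l4 = leaves[leaf]
            # encode redundancy by blank cells half the time to exercise inheritance
            if l4 == l3 and rng.random() < 0.5:
                l4 = ""
                if l3 == l2 and rng.random() < 0.5:
                    l3 = ""
            ann_rows.append([g, l1, l2, l3, l4])
    _write_tsv(os.path.join(out_dir, "annotations.tsv"),
               ["gene_id", "level1", "level2", "level3", "level4"], ann_rows)

    # ---- maps ------------------------------------------------------------
    maps_dir = os.path.join(out_dir, "maps")
    os.makedirs(maps_dir, exist_ok=True)
    if spec.n_maps > n_leaves:
        raise DomainError("n_maps cannot exceed the number of leaf categories")
    map_leaves = sorted(rng.choice(n_leaves, size=spec.n_maps, replace=False).tolist())
    map_files, map_ids = [], []
    for mi, leaf in enumerate(map_leaves):
        category = leaves[leaf][3]
        rids = [rid for rid, p in rxn_pathway.items() if p == category][:8]
        path = os.path.join(maps_dir, f"map_{mi + 1:02d}.yaml")
        map_id = f"map-{mi + 1:02d}"
        _write_map_yaml(path, map_id, category, rids, rxn_rows, rxn_pathway)
        map_files.append(path)
        map_ids.append(map_id)

    # ---- ground truth ----------------------------------------------------
    met_pathways: dict[str, set] = {}
    for r in rxn_rows:
        if r["rtype"] != "enzymatic":
            continue
        for side in r["equation"].replace("<=>", "->").split("->"):
            for term in side.split("+"):
                abbr = term.strip().split("[", 1)[0]
                if abbr:
                    met_pathways.setdefault(abbr, set()).add(rxn_pathway[r["rxn_id"]])
    n_multi_true = sum(1 for g in genes if len(set(assignment[g])) > 1)
    manifest = {
        "spec": {**asdict(spec),
                 "planted_transport": [list(t) for t in spec.planted_transport]},
        "counts": {
            "genes": len(genes), "metabolites": len(met_entries), "reactions": len(rxn_rows),
            "categories_per_level": {
                str(k + 1): len({p[k] for p in leaves}) for k in range(4)
            },
        },
        "gene_paths": {g: sorted(list(leaves[i]) for i in set(assignment[g])) for g in genes},
        "multi_count": n_multi_true,
        "multi_fraction": n_multi_true / len(genes),
        "met_pathway_counts": {a: len(ps) for a, ps in sorted(met_pathways.items())},
        "transport_classes": {a: [t] for a, t in transports},
        "reaction_pathways": rxn_pathway,
        "map_ids": map_ids,
        "map_files": [os.path.basename(p) for p in map_files],
        "enriched_category": leaves[enriched_leaf][3] if enriched_leaf is not None else None,
        "files": {"genes": "genes.tsv", "metabolites": "metabolites.tsv",
                  "reactions": "reactions.tsv", "annotations": "annotations.tsv"},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _random_rule(gene_pool, rng) -> str:
    if not gene_pool:
        return ""
    k = min(len(gene_pool), int(rng.integers(1, 4)))
    picks = [gene_pool[i] for i in rng.choice(len(gene_pool), size=k, replace=False)]
    if k == 1:
        return picks[0]
    if k == 2:
        return "&".join(picks) if rng.random() < 0.4 else "|".join(picks)
    return f"{picks[0]}&{picks[1]}|{picks[2]}" if rng.random() < 0.3 else "|".join(picks)


def _write_map_yaml(path, map_id, category, rids, rxn_rows, rxn_pathway):
    by_id = {r["rxn_id"]: r for r in rxn_rows}
    refs: list[str] = []
    for rid in rids:
        eq = by_id[rid]["equation"].replace("<=>", "->")
        for side in eq.split("->"):
            for term in side.split("+"):
                t = term.strip()
                if t and t not in refs:
                    refs.append(t)
    cols = 5
    nodes = []
    for i, ref in enumerate(refs):
        nodes.append({
            "met": ref, "x": 90 + (i % cols) * 140, "y": 60 + (i // cols) * 100,
            "terminal": i == 0, "main_terminus": i == 0,
        })
    pos = {n["met"]: (n["x"], n["y"]) for n in nodes}
    edges = []
    for rid in rids:
        eq = by_id[rid]["equation"].replace("<=>", "->")
        lhs, rhs = eq.split("->")
        s_ref = lhs.split("+")[0].strip()
        p_ref = rhs.split("+")[0].strip()
        (x1, y1), (x2, y2) = pos[s_ref], pos[p_ref]
        edges.append({
            "reaction": rid,
            "waypoints": [[x1, y1 + 6], [x2, y2 + 6]],
            "label_anchor": [(x1 + x2) / 2, (y1 + y2) / 2 - 8],
        })
    rows = (len(refs) + cols - 1) // cols
    doc = {
        "map": {
            "id": map_id, "title": category, "level": 4, "category": category,
            "canvas": {"width": 90 + cols * 140 + 80, "height": 60 + rows * 100 + 140},
        },
        "nodes": nodes,
        "edges": edges,
        "boxes": [],
        "regions": [],
        "reaction_pathways": {rid: rxn_pathway[rid] for rid in rids},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _write_tsv(path, header, rows):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# PEA input generation

def build_annotation_set(spec: ToyModelSpec):
    """In-memory annotation set for a spec, without touching the filesystem.

    Returns ``(AnnotationSet, info)`` where info carries the leaf paths and
    the planted enriched category name (or None).
    """
    from .annotation import AnnotationRecord, AnnotationSet

    leaves, genes, assignment, enriched_leaf = _universe(spec)
    records = [
        AnnotationRecord(g, *leaves[i])
        for g in genes
        for i in sorted(set(assignment[g]))
    ]
    info = {
        "leaves": leaves,
        "enriched_category": leaves[enriched_leaf][3] if enriched_leaf is not None else None,
    }
    return AnnotationSet(records), info


def sample_pea_genes(spec: ToyModelSpec) -> tuple[list[str], dict]:
    """Draw the planted-enrichment gene list in memory.

    ``spec.planted_enriched`` must define ``category_size``, ``k_in_list``
    and ``n_background``: the list contains ``k_in_list`` genes from the
    planted category plus ``n_background`` genes drawn outside it.  Returns
    the list and the expected (M, N, n, k, category) for the planted
    category.
    """
    if not spec.planted_enriched:
        raise DomainError("spec.planted_enriched must be set for PEA input generation")
    pe = spec.planted_enriched
    k, bg = pe["k_in_list"], pe.get("n_background", 0)
    leaves, genes, assignment, enriched_leaf = _universe(spec)
    members = sorted(g for g in genes if enriched_leaf in assignment[g])
    outside = sorted(g for g in genes if enriched_leaf not in assignment[g])
    if k > len(members) or bg > len(outside):
        raise DomainError("planted enrichment infeasible for this universe")
    rng = np.random.default_rng(spec.seed + 2)
    chosen = [members[i] for i in rng.choice(len(members), size=k, replace=False)]
    chosen += [outside[i] for i in rng.choice(len(outside), size=bg, replace=False)]
    expected = {
        "category": leaves[enriched_leaf][3], "level": 4,
        "M": len(genes), "N": k + bg, "n": len(members), "k": k,
    }
    return chosen, expected


def generate_pea_input(spec: ToyModelSpec, path) -> dict:
    """Write the planted-enrichment gene list of :func:`sample_pea_genes`
    as a plain-text file; returns the expected-values dict."""
    chosen, expected = sample_pea_genes(spec)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# synthetic gene list with a planted enrichment\n")
        for g in chosen:
            fh.write(g + "\n")
    return expected
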