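"""Four-level gene-to-pathway annotation hierarchy.

Every gene of the metabolic model is assigned to one or more pathways (or
enzyme categories) at four nested levels of resolution: Level 1 is the
broadest grouping (ten classes such as amino acids, lipids, carbohydrates),
Levels 2-4 successively refine it.  A branch that cannot be subdivided
further is carried down unchanged, so higher levels contain redundant
copies of coarser names; in the master table the four column counts are
10/61/79/85 and about a third of genes belong to more than one pathway.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError, SchemaError, UnknownIdError

LEVELS = (1, 2, 3, 4)


@dataclass(frozen=True)
class AnnotationRecord:
    """One full (L1, L2, L3, L4) pathway path for one gene."""

    gene_id: str
    level1: str
    level2: str
    level3: str
    level4: str

    def path(self) -> tuple[str, str, str, str]:
        return (self.level1, self.level2, self.level3, self.level4)

    def at(self, level: int) -> str:
        return self.path()[level - 1]


@dataclass(frozen=True)
class AnnotationStats:
    categories_per_level: dict[int, int]
    multi_pathway_fraction: float  # exact fraction in [0, 1]
    genes_total: int

    @property
    def multi_pathway_percent(self) -> int:
        """Display form: percentage rounded to the nearest integer."""
        return round(self.multi_pathway_fraction * 100)


class AnnotationSet:
    """The annotation hierarchy with per-level category -> gene-set indexes."""

    def __init__(self, records):
        # dedupe while preserving first-seen order
        seen = set()
        self.records: list[AnnotationRecord] = []
        for rec in records:
            if rec not in seen:
                seen.add(rec)
                self.records.append(rec)
        self.universe: set[str] = {r.gene_id for r in self.records}
        # (level, name) -> set of genes
        self._index: dict[tuple[int, str], set[str]] = {}
        self._by_gene: dict[str, list[AnnotationRecord]] = {}
        for rec in self.records:
            for lvl in LEVELS:
                self._index.setdefault((lvl, rec.at(lvl)), set()).add(rec.gene_id)
            self._by_gene.setdefault(rec.gene_id, []).append(rec)

    def __len__(self):
        return len(self.records)

    def categories_at_level(self, level: int) -> list[str]:
        """Distinct category names at a level, lexicographically ordered."""
        _check_level(level)
        return sorted({name for (lvl, name) in self._index if lvl == level})

    def genes_in_category(self, level: int, name: str) -> set[str]:
        """The gene set of one category; its size is the PEA category size n."""
        _check_level(level)
        key = (level, name)
        if key not in self._index:
            candidates = difflib.get_close_matches(name, self.categories_at_level(level), n=3)
            hint = f" (did you mean: {', '.join(candidates)}?)" if candidates else ""
            raise UnknownIdError(f"unknown category {name!r} at level {level}{hint}")
        return set(self._index[key])

    def pathways_of_gene(self, gene_id: str) -> list[tuple[str, str, str, str]]:
        """All distinct full (L1,L2,L3,L4) paths of a gene; [] if unannotated."""
        out, seen = [], set()
        for rec in self._by_gene.get(gene_id, ()):
            if rec.path() not in seen:
                seen.add(rec.path())
                out.append(rec.path())
        return out

    def children(self, level: int, name: str) -> list[str]:
        """Distinct level+1 category names appearing under a category."""
        _check_level(level)
        if level == 4:
            return []
        return sorted({r.at(level + 1) for r in self.records if r.at(level) == name})


def _check_level(level):
    if level not in LEVELS:
        raise DomainError(f"level must be in 1..4, got {level!r}")


def load_annotations(path) -> AnnotationSet:
    """Load the master annotation table.

    An empty level-k cell (k >= 2) inherits the level-(k-1) value, so tables
    that encode redundancy either by repetition or by blank cells load
    identically.  An empty level1 cell is a schema error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = ["gene_id", "level1", "level2", "level3", "level4"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in required]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s): {', '.join(unknown)}")
    records = []
    for i, row in df.iterrows():
        gene = row["gene_id"].strip()
        levels = [row[f"level{k}"].strip() for k in LEVELS]
        if not gene:
            raise SchemaError(f"{path}: empty gene_id at data row {i + 1}")
        if not levels[0]:
            raise SchemaError(f"{path}: empty level1 cell at data row {i + 1}")
        for k in range(1, 4):  # redundancy propagation
            if not levels[k]:
                levels[k] = levels[k - 1]
        records.append(AnnotationRecord(gene, *levels))
    return AnnotationSet(records)


def annotation_stats(aset: AnnotationSet) -> AnnotationStats:
    """Category counts per level and the multi-pathway gene fraction.

    A gene counts as multi-pathway when it owns more than one distinct full
    (L1,L2,L3,L4) path — the strictest reading of multiple assignment.
    """
    counts = {lvl: len(aset.categories_at_level(lvl)) for lvl in LEVELS}
    paths_per_gene: dict[str, set] = {}
    for rec in aset.records:
        paths_per_gene.setdefault(rec.gene_id, set()).add(rec.path())
    total = len(paths_per_gene)
    multi = sum(1 for p in paths_per_gene.values() if len(p) > 1)
    frac = multi / total if total else 0.0
    return AnnotationStats(categories_per_level=counts, multi_pathway_fraction=frac, genes_total=total)


def export_gmt(aset: AnnotationSet, level: int, path) -> None:
    """Write one level of the hierarchy as a GMT gene-set file.

    One line per category: name, description ``WormPaths L<level>``, then the
    deduplicated, sorted gene ids, all tab-separated.
    """
    _check_level(level)
    with open(path, "w", encoding="utf-8") as fh:
        for name in aset.categories_at_level(level):
            genes = sorted(aset.genes_in_category(level, name))
            fh.write("\t".join([name, f"WormPaths L{level}", *genes]) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file back into a category -> gene-set mapping."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SchemaError(f"{path}: GMT line needs name and description: {line!r}")
            out[parts[0]] = set(parts[2:])
    return out


def write_annotations(aset: AnnotationSet, path) -> None:
    """Serialize an annotation set back to the TSV dialect (fully explicit)."""
    rows = [
        {"gene_id": r.gene_id, "level1": r.level1, "level2": r.level2,
         "level3": r.level3, "level4": r.level4}
        for r in aset.records
    ]
    pd.DataFrame(rows, columns=["gene_id", "level1", "level2", "level3", "level4"]).to_csv(
        path, sep="\t", index=False
    )
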