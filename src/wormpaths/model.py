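"""Compartmentalized metabolic model: genes, metabolites, reactions, gene rules.

The model mirrors the shape of a genome-scale C. elegans reconstruction
(on the order of 1314 genes, 907 compartment-specific metabolites and 2230
reactions).  Metabolites are identified by a BiGG-style abbreviation plus a
compartment code, written ``abbr[comp]`` in files; reactions carry boolean
gene rules in the flat display convention used on pathway maps: ``|``
separates alternative enzymes (OR) and ``&`` joins obligate complex
subunits (AND), with ``&`` binding tighter than ``|`` and no parentheses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import CrossRefError, DomainError, RuleParseError, SchemaError, UnknownIdError

#: Sentinel used in metabolite tables when no structure image exists.
NO_STRUCTURE = "NONE"

#: Compartment codes that participate in the transport legend.
LEGEND_COMPARTMENTS = {"c", "m", "e"}

DEFAULT_COMPARTMENTS = {"c": "cytosol", "m": "mitochondria", "e": "extracellular"}


@dataclass(frozen=True)
class Gene:
    id: str
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.id:
            raise SchemaError("gene id must be non-empty")


@dataclass(frozen=True)
class Metabolite:
    """One compartment-specific metabolite species.

    Identity is the compound key ``(id, compartment)``; the bare abbreviation
    is what maps display, the full ``abbr[comp]`` token is what files use.
    """

    id: str
    compartment: str
    name: str = ""
    formula: str = ""
    structure_ref: str = NO_STRUCTURE

    @property
    def ref(self) -> str:
        return f"{self.id}[{self.compartment}]"


@dataclass(frozen=True)
class GeneRule:
    """OR-of-AND boolean gene association: ``clauses`` is an ordered tuple of
    AND-chains, each an ordered tuple of gene ids."""

    clauses: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        if not self.clauses or any(not c for c in self.clauses):
            raise RuleParseError("gene rule must contain no empty clause")

    def genes(self) -> set[str]:
        return {g for chain in self.clauses for g in chain}

    def __str__(self) -> str:
        return "|".join("&".join(chain) for chain in self.clauses)


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: tuple[tuple[str, float], ...]  # (met ref "abbr[comp]", stoich > 0)
    products: tuple[tuple[str, float], ...]
    reversible: bool = False
    rtype: str = "enzymatic"  # enzymatic | transport
    rule: GeneRule | None = None
    rule_raw: str = ""  # verbatim rule text; kept even when parsing failed (lenient load)
    co_reactants: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.substrates or not self.products:
            raise SchemaError(f"reaction {self.id!r}: needs at least one substrate and one product")
        if self.rtype not in ("enzymatic", "transport"):
            raise SchemaError(f"reaction {self.id!r}: rtype must be enzymatic or transport")
        sides = {m for m, _ in self.substrates} | {m for m, _ in self.products}
        bad = [c for c in self.co_reactants if c not in sides]
        if bad:
            raise SchemaError(
                f"reaction {self.id!r}: co_reactants not among participants: {', '.join(bad)}"
            )

    @property
    def orphan(self) -> bool:
        return self.rule is None and not self.rule_raw

    def metabolite_refs(self) -> list[str]:
        seen, out = set(), []
        for m, _ in (*self.substrates, *self.products):
            if m not in seen:
                seen.add(m)
                out.append(m)
        return out


_TOKEN_RE = re.compile(r"[^\s|&]+")


def parse_gene_rule(text: str) -> GeneRule:
    """Parse a flat OR-of-AND gene rule string.

    Grammar: ``rule := chain ('|' chain)*; chain := gene ('&' gene)*``.
    Whitespace around separators is ignored; gene tokens are preserved
    verbatim.  Empty chains (``a||b``, leading/trailing separators) raise
    :class:`RuleParseError` naming the offending position.
    """
    if text is None or not text.strip():
        raise RuleParseError("empty gene rule", text=text or "")
    clauses = []
    for clause_text in _split_keeping_pos(text):
        chain = []
        for gene_text, gpos in clause_text:
            token = gene_text.strip()
            if not token:
                raise RuleParseError(
                    f"empty gene token at position {gpos} in rule {text!r}",
                    text=text,
                    position=gpos,
                )
            if not _TOKEN_RE.fullmatch(token):
                raise RuleParseError(
                    f"malformed gene token {token!r} at position {gpos} in rule {text!r}",
                    text=text,
                    position=gpos,
                )
            chain.append(token)
        clauses.append(tuple(chain))
    return GeneRule(tuple(clauses))


def _split_keeping_pos(text: str):
    """Split on '|' then '&', yielding per-clause lists of (token_text, start_pos)."""
    clauses = []
    parts = []
    start = 0
    for i, ch in enumerate(text):
        if ch == "|":
            parts.append((text[start:i], start))
            start = i + 1
    parts.append((text[start:], start))
    for clause_text, cstart in parts:
        chain = []
        s = 0
        for j, ch in enumerate(clause_text):
            if ch == "&":
                chain.append((clause_text[s:j], cstart + s))
                s = j + 1
        chain.append((clause_text[s:], cstart + s))
        clauses.append(chain)
    return clauses


class MetabolicModel:
    """Validated in-memory model with O(1) lookups by id."""

    def __init__(self, genes, metabolites, reactions, compartments=None):
        self.compartments: dict[str, str] = dict(compartments or DEFAULT_COMPARTMENTS)
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.id in self.genes:
                raise SchemaError(f"duplicate gene id {g.id!r}")
            self.genes[g.id] = g
        self.metabolites: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.ref in self.metabolites:
                raise SchemaError(f"duplicate metabolite {m.ref!r}")
            self.metabolites[m.ref] = m
        self.reactions: dict[str, Reaction] = {}
        for r in reactions:
            if r.id in self.reactions:
                raise SchemaError(f"duplicate reaction id {r.id!r}")
            self.reactions[r.id] = r
        self._alias_index = {}
        for g in self.genes.values():
            for a in g.aliases:
                self._alias_index.setdefault(a, g.id)
        self.validate()

    # -- queries -----------------------------------------------------------
    def n_genes(self) -> int:
        return len(self.genes)

    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def n_reactions(self) -> int:
        return len(self.reactions)

    def metabolite_compartments(self, met_id: str) -> set[str]:
        comps = {m.compartment for m in self.metabolites.values() if m.id == met_id}
        if not comps:
            raise UnknownIdError(f"unknown metabolite abbreviation {met_id!r}")
        return comps

    def resolve_alias(self, token: str) -> str | None:
        if token in self.genes:
            return token
        return self._alias_index.get(token)

    def reactions_of_metabolite(self, ref_or_id: str) -> list[Reaction]:
        """Reactions involving a metabolite, by full ref or bare abbreviation."""
        bare = "[" not in ref_or_id
        out = []
        for r in self.reactions.values():
            for ref in r.metabolite_refs():
                if ref == ref_or_id or (bare and ref.split("[", 1)[0] == ref_or_id):
                    out.append(r)
                    break
        return out

    # -- validation --------------------------------------------------------
    def validate(self):
        missing_mets, missing_genes = set(), set()
        for r in self.reactions.values():
            for ref in r.metabolite_refs():
                if ref not in self.metabolites:
                    missing_mets.add(ref)
            if r.rule is not None:
                for g in r.rule.genes():
                    if g not in self.genes:
                        missing_genes.add(g)
        if missing_mets or missing_genes:
            items = sorted(missing_mets) + sorted(missing_genes)
            raise CrossRefError(
                "unresolved references in reactions: " + ", ".join(items),
                missing=items,
            )
        for r in self.reactions.values():
            if r.rtype == "transport":
                self._check_transport(r)

    def _check_transport(self, r: Reaction):
        # a transport must move at least one abbreviation between two
        # distinct compartments (same id on both sides, different comps)
        subs = {m.rsplit("[", 1)[0]: m[:-1].rsplit("[", 1)[1] for m, _ in r.substrates}
        prods = {m.rsplit("[", 1)[0]: m[:-1].rsplit("[", 1)[1] for m, _ in r.products}
        moved = [a for a in subs if a in prods and subs[a] != prods[a]]
        if not moved:
            raise SchemaError(
                f"transport reaction {r.id!r} does not move any metabolite between compartments"
            )

    def transported_pairs(self, r: Reaction) -> list[tuple[str, str, str]]:
        """(abbreviation, from_comp, to_comp) for every species a transport moves."""
        subs = {m.rsplit("[", 1)[0]: m[:-1].rsplit("[", 1)[1] for m, _ in r.substrates}
        prods = {m.rsplit("[", 1)[0]: m[:-1].rsplit("[", 1)[1] for m, _ in r.products}
        return [(a, subs[a], prods[a]) for a in subs if a in prods and subs[a] != prods[a]]


def genes_of_reaction(model: MetabolicModel, rid: str) -> set[str]:
    """Flat union of gene ids in a reaction's rule; empty set for orphans."""
    if rid not in model.reactions:
        raise UnknownIdError(f"unknown reaction id {rid!r}")
    r = model.reactions[rid]
    return r.rule.genes() if r.rule is not None else set()


# ---------------------------------------------------------------------------
# TSV dialects

_MET_REF_RE = re.compile(r"^(?P<coef>\d+(?:\.\d+)?\s+)?(?P<abbr>[^\s\[\]]+)\[(?P<comp>[^\s\[\]]+)\]$")


def parse_metabolite_term(term: str) -> tuple[str, float]:
    """Parse one equation term like ``pep[c]`` or ``2 atp[c]`` -> (ref, coef)."""
    m = _MET_REF_RE.match(term.strip())
    if not m:
        raise SchemaError(f"malformed metabolite term {term!r} (expected 'abbr[comp]')")
    coef = float(m.group("coef")) if m.group("coef") else 1.0
    if coef <= 0:
        raise SchemaError(f"stoichiometry must be positive in term {term!r}")
    return f"{m.group('abbr')}[{m.group('comp')}]", coef


def parse_equation(eq: str) -> tuple[list, list, bool]:
    """Parse ``a[c] + b[c] <=> c[c]`` (reversible) or ``->`` (irreversible)."""
    if "<=>" in eq:
        lhs, rhs = eq.split("<=>", 1)
        rev = True
    elif "->" in eq:
        lhs, rhs = eq.split("->", 1)
        rev = False
    else:
        raise SchemaError(f"equation {eq!r} lacks a '->' or '<=>' arrow")
    subs = [parse_metabolite_term(t) for t in lhs.split("+") if t.strip()]
    prods = [parse_metabolite_term(t) for t in rhs.split("+") if t.strip()]
    if not subs or not prods:
        raise SchemaError(f"equation {eq!r} must have metabolites on both sides")
    return subs, prods, rev


def _read_tsv(path, required_cols):
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def load_model(gene_table, metabolite_table, reaction_table, strict_rules: bool = True) -> MetabolicModel:
    """Load a model from the three TSV tables and validate all cross-references.

    With ``strict_rules=False`` an unparseable gene rule is kept verbatim on
    the reaction (``rule=None``, ``rule_raw`` set) for the linter to report
    instead of aborting the load.
    """
    gdf = _read_tsv(gene_table, ["gene_id", "aliases"])
    genes = []
    for i, row in gdf.iterrows():
        if not row["gene_id"].strip():
            raise SchemaError(f"{gene_table}: empty gene_id at data row {i + 1}")
        aliases = tuple(a.strip() for a in row["aliases"].split(",") if a.strip())
        genes.append(Gene(row["gene_id"].strip(), aliases))

    mdf = _read_tsv(metabolite_table, ["met_id", "compartment", "name", "formula", "structure_ref"])
    mets = []
    for i, row in mdf.iterrows():
        mets.append(
            Metabolite(
                id=row["met_id"].strip(),
                compartment=row["compartment"].strip(),
                name=row["name"].strip(),
                formula=row["formula"].strip(),
                structure_ref=row["structure_ref"].strip() or NO_STRUCTURE,
            )
        )

    rdf = _read_tsv(reaction_table, ["rxn_id", "equation", "rtype", "gene_rule", "co_reactants"])
    rxns = []
    for i, row in rdf.iterrows():
        subs, prods, rev = parse_equation(row["equation"])
        rule_text = row["gene_rule"].strip()
        rule = None
        if rule_text:
            try:
                rule = parse_gene_rule(rule_text)
            except RuleParseError:
                if strict_rules:
                    raise
        co = tuple(c.strip() for c in row["co_reactants"].split(",") if c.strip())
        rxns.append(
            Reaction(
                id=row["rxn_id"].strip(),
                substrates=tuple(subs),
                products=tuple(prods),
                reversible=rev,
                rtype=row["rtype"].strip(),
                rule=rule,
                rule_raw=rule_text,
                co_reactants=co,
            )
        )
    return MetabolicModel(genes, mets, rxns)
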