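# Methods

This note documents the statistical model, the conventions the package
encodes, the defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and known limitations.

## 1. Data model

**Model tables.** Three tab-separated tables define the metabolic
model: genes (`gene_id`, optional description), metabolites
(`abbr`, `name`, `compartment`, `structure`; a metabolite instance is
identified by `abbr[compartment]`, e.g. `pyr[c]`; metabolites without a
defined structure carry the sentinel `NONE`), and reactions
(`reaction_id`, `equation`, `type` ∈ {enzymatic, transport},
`gene_rule`, optional `co_reactants`). Equations use
`2 atp[c] + ...` coefficient syntax with `->` (irreversible) or `<=>`
(reversible). A transport reaction must move at least one abbreviation
between two compartments; validation enforces this along with full
cross-referencing of genes and metabolites.

**Gene rules.** Gene–reaction associations are flat boolean
expressions: `|` separates alternative enzymes, `&` joins obligate
complex subunits, `&` binds tighter than `|`, and parentheses are not
part of the grammar (the display convention on the maps is flat).
Parse errors report the character position. A rule's gene set is the
union over all clauses.

**Annotation hierarchy.** Each gene has one or more records with four
pathway levels, Level 1 broadest. When a branch cannot be subdivided,
the parent name repeats at deeper levels; on disk this redundancy may
be written either explicitly or as blank cells, and the loader treats
the two identically (a blank level-k cell, k ≥ 2, inherits level-(k−1);
a blank level-1 cell is a schema error). A gene is *multi-pathway* when
it has more than one distinct full (L1, L2, L3, L4) path — the
strictest reading of multiple assignment; per-level overlap would give
larger numbers. Category matching is case-sensitive; unknown category
names raise an error with close-match suggestions rather than silently
returning an empty set.

## 2. Pathway enrichment analysis

Let *M* be the size of the annotated gene universe, *N* the number of
input genes found in the universe (the *metabolic hits*; unmatched
input identifiers are reported but excluded), *n* the size of a
category at the level under test, and *k* the overlap between the hits
and the category. Under the null hypothesis that the hits are an
unordered sample without replacement from the universe,
K ~ Hypergeometric(M, n, N):

  P(K = k) = C(n, k) · C(M−n, N−k) / C(M, N)

- **Enrichment p-value**: P(K ≥ k), the upper tail *including* k.
- **Depletion p-value**: P(K ≤ k), the lower tail *including* k.
- **Score**: k / n, the fraction of the category recovered.

Because both tails include the observed count, they satisfy
p_enrich + p_deplete = 1 + P(K = k), which the test suite asserts on
every emitted row.

**Numerics.** Tails are computed with `scipy.stats.hypergeom`
(`sf(k−1, M, n, N)` and `cdf(k, M, n, N)`), with analytic shortcuts
returning exactly 1.0 at the degenerate boundaries k ≤ max(0, n+N−M)
and k ≥ min(n, N) — so empty or all-gene inputs give p_enrich = 1
exactly, not 1 − ε. The implementation is checked against an
independent arbitrary-precision rational oracle
(`fractions.Fraction` + `math.comb`) over every valid (M ≤ 30, n, N, k)
combination; the observed worst absolute error is ~3×10⁻¹⁶ and the
asserted tolerance is 1e−12, a loose bound for double-precision tails
at these problem sizes.

**Multiple testing.** Stored p-values are deliberately uncorrected so
that enrichment strength is not underestimated when categories overlap
across levels; the report includes an advisory Bonferroni column,
pass = p_enrich < α / n_test with α = 0.05 and n_test the number of
categories tested at that row's level. Rows are ordered by level, then
ascending p_enrich, with ties broken by category name for determinism.
Categories with n = 0 genes at a level are skipped (no test is
defined). The HTML report colors cells by −log₁₀(p) on white→red
(enrichment) and white→blue (depletion) ramps saturating at 10, i.e.
p = 10⁻¹⁰; the saturation point only affects display.

## 3. Connectivity and terminal metabolites

**Pathway count per metabolite.** Each enzymatic reaction maps to a
Level-4 pathway, either declared explicitly by the map definition or
inferred as the union of its genes' Level-4 annotations. A
metabolite's pathway count pools all compartment instances of its
abbreviation and ignores transport reactions (transport is not a
pathway). Counts are displayed as grayscale bins 1 / 2 / 3 / ≥4 —
four bins keep the map legend readable while separating the common
low counts exactly.

**Transportability.** Two transport classes are tracked: `C_E`
(cytosol ↔ extracellular) and `M_C` (mitochondrion ↔ cytosol), the two
membrane crossings drawn on the maps; other compartment pairs are
ignored by the legend annotation.

**Terminal classification.** A declared terminal metabolite on a map is
classified by a fixed decision cascade:

1. `MAIN_TERMINUS` — it is the map's designated end product;
2. `PATHWAY_BOXES` — it participates in 1..box_threshold *other*
   pathways: each is drawn as a named pathway box;
3. `TRANSPORT_ENDPOINT` — no other pathways, but it is transportable:
   drawn with its transport mark only;
4. `OTHER_BOX` — no other pathways, not transportable: a generic
   "other" box;
5. `LINK_ONLY` — more than box_threshold other pathways: a link-out
   instead of boxes, to avoid unreadable box stacks.

`box_threshold` defaults to 2 (at most two named boxes fit a terminal
cleanly); it is a CLI flag, and a variant of 4 is reasonable for
sparser maps. The linter's `TERMINAL_RULE_VIOLATION` compares this
expected classification against what a map actually draws.

## 4. SVG rendering and linting

Maps are authored as YAML (canvas, regions, nodes with coordinates,
edges as reaction + ≥2 waypoints, terminal/box declarations, optional
explicit reaction→pathway assignments). Rendering is a pure function
of the map definition, model, annotations and style, and emits
byte-identical output across runs — determinism makes diffs and
caching meaningful.

Style defaults: black `#000000` enzymatic edges, sea-green `#2e8b57`
transport edges, blue `#1f4fd8` gene labels, orange `#e07b00`
co-reactants — dark, print-safe colors that remain distinguishable in
grayscale by context (edge vs. label vs. superscript position). All
colors are configurable and hex-validated. Structural CSS classes
(`wp-gene`, `wp-met`, `wp-coreactant`, `wp-legend`) make the SVG
machine-readable: `extract_map_genes` recovers a map's gene set by
splitting `wp-gene` texts on `|`/`&`, and the test suite asserts this
round-trips the model's gene rules exactly. Every map gets exactly one
legend group. Metabolite nodes are links (`#met-<abbr>` by default)
with a hover card; metabolites with structure `NONE` get the card
placeholder "Structure not available" plus a lint warning.

Lint codes and severities: errors (`DUP_NODE`, `MET_UNRESOLVED`,
`REACTION_UNRESOLVED`, `RULE_PARSE_ERROR`, `GENE_NOT_IN_ANNOTATIONS`)
are conditions that make a map wrong against the model; warnings
(`GENE_LEVEL_MISMATCH`, `ORPHAN_NODE`, `TERMINAL_RULE_VIOLATION`)
flag likely authoring mistakes that still render. The CLI exits 1 iff
errors are present.

## 5. Synthetic fixture generator

All fixtures are generated at run time from a `ToyModelSpec` by a pure
function of a `numpy.random.default_rng(seed)` stream — no binary or
bulky data ships with the package, and every ground-truth quantity is
recorded in `manifest.json` for verification.

What it emulates: the four-level hierarchy with exact per-level
category counts (built by subdividing a controlled number of parents,
carrying undivided branches down redundantly), an exact target
multi-pathway fraction, a canonical fully-subdivided chain under
"lipids" (short-chain fatty acid degradation → propionate degradation
→ propionate shunt), a designated gene with four distinct pathway
assignments, planted transportable metabolites in both legend classes,
a planted enriched category with exact (n, k, N), and a map inventory
with declared terminals and explicit reaction→pathway assignments.

What it does not emulate: real stoichiometry, mass balance,
thermodynamics, realistic network topology (reactions connect randomly
chosen metabolites), real gene/metabolite nomenclature (names are
random but format-conforming), or curation noise.

`master_shaped(seed)` produces the full-scale configuration the
package targets — 1314 genes, 907 metabolites, 2230 reactions,
10/61/79/85 categories, 32% multi-pathway genes, 62 maps, and the
four-pathway gene `alh-2` — as exact construction targets of the
generator, so the statistics pipeline is exercised at realistic size.

## 6. Verification

- Unit and property tests (hypothesis, derandomized) cover the rule
  parser, loaders, PEA math, connectivity, rendering and linting.
- `tests/test_acceptance.py` holds the end-to-end checks: the exact
  hypergeometric oracle sweep, the tail identity, degenerate inputs at
  M = 1314, exact and stochastic planted-enrichment recovery (top-1 in
  > 95 of 100 seeds), the full-scale shape statistics, SVG round-trip
  plus eight single-fault lint mutations each detected by exactly its
  code, and the terminal-classification archetypes.
- `scripts/acceptance.py` recomputes the same quantities from scratch
  and writes them as JSON.

## 7. Limitations

- The hypergeometric null assumes exchangeable genes; co-regulation or
  gene-family structure in real lists inflates significance.
- Uncorrected p-values are intentional but mean downstream users must
  apply their own multiple-testing policy; the Bonferroni column is
  advisory only.
- Pathway inference for reactions without explicit assignments uses the
  union of gene annotations, which over-counts for promiscuous genes.
- Layout is author-supplied; the renderer performs no automatic layout
  or overlap avoidance.
- Synthetic fixtures validate the pipeline's mechanics and statistics,
  not biological conclusions.
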