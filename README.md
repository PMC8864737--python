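# wormpaths

Multi-level metabolic pathway annotation, hypergeometric pathway
enrichment analysis (PEA), metabolite connectivity classification, and
standardized SVG pathway-map rendering/linting for a compartmentalized
genome-scale metabolic model of *Caenorhabditis elegans*.

The package is aimed at researchers who work with the worm's
genome-scale metabolic reconstruction (1314 genes, 907
compartment-specific metabolites, 2230 reactions) and want to

- keep gene-to-pathway assignments in a **four-level hierarchy** — from
  ten broad classes (amino acids, carbohydrates, lipids, …) at Level 1
  down to fine pathways (e.g. the propionate shunt) at Level 4, with
  redundancy carried downward when a branch cannot be subdivided;
- run **pathway enrichment analysis** of a gene list against that
  hierarchy at any level;
- export levels as **GMT gene sets** for GSEA-style tools;
- render hand-laid-out pathway maps to a **standardized SVG** template
  (black enzymatic / green transport edges, blue gene labels, orange
  co-reactants, per-metabolite pathway-count squares and transport
  circles, a legend on every map) and **lint** maps against the model
  and annotation tables.

## The statistic

For a user gene list, the overlap with the model's gene universe (size
*M*) defines the *metabolic hits* (size *N*). For each category of size
*n* at each level, with *k* category genes among the hits:

- **enrichment score** = *k*/*n*;
- **enrichment p-value** = P(K ≥ k) and **depletion p-value** = P(K ≤ k)
  under the hypergeometric distribution K ~ Hypergeom(M, n, N), both
  tails *including k*.

No multiple-testing correction is applied to the stored p-values (so
enrichment strength is not underestimated); the report adds an advisory
Bonferroni pass/fail column at threshold α/n_test, where n_test is the
number of categories at the level of interest.

Gene–reaction associations use the flat boolean display convention of
the maps: `pck-1|pck-2|pck-3` for alternative enzymes (OR) and
`pdha-1&pdhb-1` for obligate complex subunits (AND), with `&` binding
tighter than `|`.

## Worked example

The package ships a deterministic fixture generator, so a complete
example needs no external data. Generate a 120-gene toy universe with a
planted enrichment (10-gene category, 8 of them in a 20-gene input
list), then run PEA:

```python
from wormpaths.fixtures import ToyModelSpec, generate_toy_model, generate_pea_input
spec = ToyModelSpec(seed=7, planted_enriched={"category_size": 10,
                                              "k_in_list": 8, "n_background": 12})
generate_toy_model(spec, "fixtures")
generate_pea_input(spec, "genes.txt")
```

(`wormpaths make-fixtures --seed 7 --out fixtures` produces the same
tables without the planted gene list.)

```sh
wormpaths stats --annotations fixtures/annotations.tsv
```

```
Level 1: 4 categories
Level 2: 8 categories
Level 3: 12 categories
Level 4: 16 categories
Genes: 120
Multi-pathway genes: 20%
```

```sh
wormpaths pea --genes genes.txt --annotations fixtures/annotations.tsv --levels 4 --out pea
head -2 pea/results.tsv
```

```
level	category	n	k	score	p_enrich	p_deplete	bonferroni_pass	category_genes_in_hits
4	amino acids pathway 1 branch 1 step 1	10	8	0.8	5.518586e-06	9.999999e-01	yes	cal-19,gum-57,mil-45,pob-23,rri-43,tgu-48,wkw-49,zac-12
```

The planted category ranks first: 8 of its 10 genes are among the 20
metabolic hits (score 0.8) and the chance of an overlap that large in a
universe of 120 is 5.5×10⁻⁶, well below the level-4 Bonferroni
threshold 0.05/16. `pea/results.html` is the same table color-coded by
−log₁₀(p).

Maps render and lint the same way:

```sh
wormpaths render --map fixtures/maps/map_01.yaml \
    --genes fixtures/genes.tsv --metabolites fixtures/metabolites.tsv \
    --reactions fixtures/reactions.tsv --annotations fixtures/annotations.tsv \
    --out map_01.svg
wormpaths lint   --map fixtures/maps/map_01.yaml \
    --genes fixtures/genes.tsv --metabolites fixtures/metabolites.tsv \
    --reactions fixtures/reactions.tsv --annotations fixtures/annotations.tsv \
    --out lint.tsv        # exit 0, "0 issue(s), 0 error(s)"
```

## Layout

- `wormpaths.model` — model tables (genes/metabolites/reactions TSV),
  gene-rule parser, validation and queries
- `wormpaths.annotation` — 4-level hierarchy, statistics, GMT export
- `wormpaths.pea` — overlap, hypergeometric tails, PEA tables and reports
- `wormpaths.connectivity` — pathway counts, transport classes,
  terminal-metabolite classification
- `wormpaths.mapgen` — YAML map definitions, SVG renderer, gene
  extraction, linter
- `wormpaths.fixtures` — deterministic synthetic data with a
  ground-truth manifest
- `wormpaths.cli` — the `wormpaths` command
  (`pea|render|lint|stats|export-gmt|make-fixtures`)

See `docs/methods.md` for the underlying model, conventions and design
choices.
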