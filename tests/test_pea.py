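"""Hypergeometric enrichment statistics against an exact rational oracle."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lxml import etree

from wormpaths.errors import DomainError
from wormpaths.fixtures import ToyModelSpec, build_annotation_set, sample_pea_genes
from wormpaths.pea import (
    bonferroni_threshold,
    compute_overlap,
    depletion_pvalue,
    enrichment_pvalue,
    hypergeom_pmf,
    read_gene_list,
    run_pea,
    write_pea_outputs,
)

# ---------------------------------------------------------------------------
# Exact arbitrary-precision oracle (independent of scipy)


def pmf_exact(M, n, N, k) -> Fraction:
    if k < max(0, n + N - M) or k > min(n, N):
        return Fraction(0)
    return Fraction(math.comb(n, k) * math.comb(M - n, N - k), math.comb(M, N))


def enrich_exact(M, n, N, k) -> Fraction:
    return sum((pmf_exact(M, n, N, i) for i in range(k, min(n, N) + 1)), Fraction(0))


def deplete_exact(M, n, N, k) -> Fraction:
    return sum((pmf_exact(M, n, N, i) for i in range(max(0, n + N - M), k + 1)), Fraction(0))


# ---------------------------------------------------------------------------


def test_pmf_worked_example():
    # C(4,0) C(16,10) / C(20,10) = 210/4845 by hypergeometric symmetry
    expect = Fraction(math.comb(16, 10), math.comb(20, 10))
    assert expect == Fraction(210, 4845)
    assert hypergeom_pmf(20, 4, 10, 0) == pytest.approx(float(expect), abs=1e-14)


def test_enrichment_worked_example():
    # P(K >= 4) = C(4,4) C(16,6) / C(20,10) = 8008/184756
    expect = Fraction(math.comb(16, 6), math.comb(20, 10))
    assert expect == Fraction(8008, 184756)
    assert enrichment_pvalue(20, 4, 10, 4) == pytest.approx(float(expect), abs=1e-14)


def test_depletion_worked_example():
    assert depletion_pvalue(20, 4, 10, 0) == pytest.approx(float(pmf_exact(20, 4, 10, 0)), abs=1e-14)


def test_boundary_conventions():
    assert enrichment_pvalue(100, 7, 13, 0) == 1.0  # k=0: total probability
    assert depletion_pvalue(100, 7, 13, 7) == 1.0  # k = min(n, N)
    assert hypergeom_pmf(50, 5, 50, 5) == pytest.approx(1.0)  # all genes are hits
    assert enrichment_pvalue(1314, 10, 1314, 10) == 1.0  # forced intersection
    assert hypergeom_pmf(20, 4, 10, 9) == 0.0  # outside support


def test_invalid_parameters_rejected():
    for bad in [(10, 11, 5, 0), (10, 5, 11, 0), (10, -1, 5, 0)]:
        with pytest.raises(DomainError):
            hypergeom_pmf(*bad)


@settings(derandomize=True, max_examples=300)
@given(st.integers(1, 30), st.data())
def test_tails_match_exact_oracle(M, data):
    n = data.draw(st.integers(0, M))
    N = data.draw(st.integers(0, M))
    lo, hi = max(0, n + N - M), min(n, N)
    k = data.draw(st.integers(lo, hi))
    assert hypergeom_pmf(M, n, N, k) == pytest.approx(float(pmf_exact(M, n, N, k)), abs=1e-12)
    assert enrichment_pvalue(M, n, N, k) == pytest.approx(float(enrich_exact(M, n, N, k)), abs=1e-12)
    assert depletion_pvalue(M, n, N, k) == pytest.approx(float(deplete_exact(M, n, N, k)), abs=1e-12)
    # both tails include k: p_e + p_d = 1 + pmf(k)
    assert enrichment_pvalue(M, n, N, k) + depletion_pvalue(M, n, N, k) == pytest.approx(
        1.0 + hypergeom_pmf(M, n, N, k), abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(st.integers(2, 25), st.data())
def test_pmf_normalizes_and_enrichment_monotone(M, data):
    n = data.draw(st.integers(1, M))
    N = data.draw(st.integers(1, M))
    lo, hi = max(0, n + N - M), min(n, N)
    total = sum(hypergeom_pmf(M, n, N, k) for k in range(lo, hi + 1))
    assert total == pytest.approx(1.0, abs=1e-12)
    tails = [enrichment_pvalue(M, n, N, k) for k in range(lo, hi + 1)]
    assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))


def test_bonferroni():
    assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.05, 85) == pytest.approx(0.05 / 85)
    with pytest.raises(DomainError):
        bonferroni_threshold(1.5, 10)
    with pytest.raises(DomainError):
        bonferroni_threshold(0.05, 0)


def test_compute_overlap_dedupe_and_unmatched():
    inp = compute_overlap(["acdh-1", " acdh-1", "notagene"], {"acdh-1", "pck-1"})
    assert inp.hits == {"acdh-1"} and inp.N == 1
    assert inp.unmatched == ("notagene",)
    assert compute_overlap([], {"a"}).N == 0
    full = compute_overlap(["a", "b"], {"a", "b"})
    assert full.N == full.M == 2
    with pytest.raises(DomainError):
        compute_overlap(["a"], set())


def test_run_pea_recovers_planted_category(toy_aset, toy_manifest, toy_spec):
    genes, exp = sample_pea_genes(toy_spec)
    table = run_pea(genes, toy_aset, levels=[4])
    assert table.inputs.M == exp["M"] and table.inputs.N == exp["N"]
    top = table.sorted_results()[0]
    assert top.category == exp["category"]
    assert (top.n, top.k) == (exp["n"], exp["k"]) and top.score == 1.0
    oracle = float(enrich_exact(exp["M"], exp["n"], exp["N"], exp["k"]))
    assert top.p_enrich == pytest.approx(oracle, abs=1e-12)
    for r in table.results:  # tail identity on every emitted row
        assert r.p_enrich + r.p_deplete == pytest.approx(
            1.0 + hypergeom_pmf(table.inputs.M, r.n, table.inputs.N, r.k), abs=1e-12)


def test_run_pea_degenerate_inputs(toy_aset):
    empty = run_pea([], toy_aset)
    assert all(r.k == 0 and r.score == 0 and r.p_enrich == 1.0 for r in empty.results)
    everything = run_pea(sorted(toy_aset.universe), toy_aset)
    assert all(r.k == r.n and r.score == 1.0 and r.p_enrich == 1.0 for r in everything.results)


def test_outputs_roundtrip_and_html_wellformed(toy_aset, toy_spec, tmp_path):
    import pandas as pd

    genes, _ = sample_pea_genes(toy_spec)
    table = run_pea(genes, toy_aset)
    paths = write_pea_outputs(table, tmp_path)
    df = pd.read_csv(paths["tsv"], sep="\t")
    assert len(df) == len(table.results)
    by_key = {(r.level, r.category): r for r in table.results}
    for _, row in df.iterrows():
        r = by_key[(row["level"], row["category"])]
        assert (row["n"], row["k"]) == (r.n, r.k)
        assert row["p_enrich"] == pytest.approx(r.p_enrich, rel=1e-5)
    levels = df["level"].tolist()
    assert levels == sorted(levels)  # deterministic ordering
    etree.parse(paths["html"])  # XML well-formedness


def test_empty_table_writes_header_only(toy_aset, tmp_path):
    table = run_pea([], toy_aset, levels=[1])
    table.results = []
    paths = write_pea_outputs(table, tmp_path)
    lines = open(paths["tsv"]).read().splitlines()
    assert len(lines) == 1 and lines[0].startswith("level\t")


def test_read_gene_list(tmp_path):
    p = tmp_path / "genes.txt"
    p.write_text("# comment\nacdh-1\n pck-1 \n\npck-1 # trailing\n")
    assert read_gene_list(p) == ["acdh-1", "pck-1", "pck-1"]
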