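"""Pathway enrichment analysis (PEA) over the annotation hierarchy.

Given a user gene list, the overlap with the metabolic universe (the model's
gene set, size M) defines the metabolic hits (size N).  For every category
of size n at every level, the strength of the intersection (size k) is the
enrichment score k/n and its significance the hypergeometric tail
probabilities: the enrichment p-value is P(K >= k) and the depletion
p-value P(K <= k), both tails including k itself.  No multiple-testing
correction is applied to the stored p-values — a Bonferroni threshold is
reported separately as advisory — so that enrichment strength is not
underestimated.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field

from scipy.stats import hypergeom

from .annotation import AnnotationSet
from .errors import DomainError

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class PEAInput:
    raw_genes: tuple[str, ...]
    hits: frozenset[str]
    universe_size: int
    unmatched: tuple[str, ...]

    @property
    def N(self) -> int:
        return len(self.hits)

    @property
    def M(self) -> int:
        return self.universe_size


@dataclass(frozen=True)
class PEAResult:
    level: int
    category: str
    n: int
    k: int
    score: float
    p_enrich: float
    p_deplete: float
    genes_in_hits: tuple[str, ...]
    bonferroni_pass: bool = False


@dataclass
class PEATable:
    inputs: PEAInput
    results: list[PEAResult]
    alpha: float = DEFAULT_ALPHA
    universe_source: str = ""
    timestamp: str = field(default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds"))

    def at_level(self, level: int) -> list[PEAResult]:
        return [r for r in self.results if r.level == level]

    def sorted_results(self) -> list[PEAResult]:
        """Deterministic report order: level asc, p_enrich asc, name asc."""
        return sorted(self.results, key=lambda r: (r.level, r.p_enrich, r.category))


def compute_overlap(raw_genes, universe, aliases=None) -> PEAInput:
    """Intersect a user gene list with the universe.

    Tokens are whitespace-trimmed and deduplicated; unmatched tokens are
    reported, not errors.  ``aliases`` optionally maps alternative tokens to
    canonical gene ids (alias expansion is off by default in the CLI).
    """
    if not universe:
        raise DomainError("universe must be non-empty")
    seen, cleaned = set(), []
    for tok in raw_genes:
        t = tok.strip()
        if t and t not in seen:
            seen.add(t)
            cleaned.append(t)
    hits, unmatched = set(), []
    for t in cleaned:
        if t in universe:
            hits.add(t)
        elif aliases and aliases.get(t) in universe:
            hits.add(aliases[t])
        else:
            unmatched.append(t)
    return PEAInput(tuple(cleaned), frozenset(hits), len(universe), tuple(unmatched))


def _check_params(M, n, N):
    if M < 0 or not (0 <= n <= M) or not (0 <= N <= M):
        raise DomainError(f"invalid hypergeometric parameters M={M}, n={n}, N={N}")


def hypergeom_pmf(M: int, n: int, N: int, k: int) -> float:
    """P(K = k) drawing N items from M of which n are marked.

    Zero outside the support [max(0, n+N-M), min(n, N)].
    """
    _check_params(M, n, N)
    if k < max(0, n + N - M) or k > min(n, N):
        return 0.0
    return float(hypergeom.pmf(k, M, n, N))


def enrichment_pvalue(M: int, n: int, N: int, k: int) -> float:
    """P(K >= k): the upper tail including k (never 1 - CDF(k))."""
    _check_params(M, n, N)
    if k <= max(0, n + N - M):
        return 1.0
    if k > min(n, N):
        return 0.0
    return float(hypergeom.sf(k - 1, M, n, N))


def depletion_pvalue(M: int, n: int, N: int, k: int) -> float:
    """P(K <= k): the lower tail including k."""
    _check_params(M, n, N)
    if k >= min(n, N):
        return 1.0
    if k < max(0, n + N - M):
        return 0.0
    return float(hypergeom.cdf(k, M, n, N))


def bonferroni_threshold(alpha: float, n_test: int) -> float:
    """The per-test significance threshold alpha / n_test."""
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if n_test < 1:
        raise DomainError(f"n_test must be >= 1, got {n_test}")
    return alpha / n_test


def run_pea(raw_genes, aset: AnnotationSet, levels=(1, 2, 3, 4), alpha: float = DEFAULT_ALPHA,
            universe=None, aliases=None, universe_source: str = "") -> PEATable:
    """Evaluate enrichment and depletion for every category at the requested levels.

    The universe defaults to the annotation set's gene universe; pass the
    model's gene set explicitly to use the full model as background.
    """
    if not levels:
        raise DomainError("levels must be non-empty")
    levels = sorted(set(levels))
    for lvl in levels:
        if lvl not in (1, 2, 3, 4):
            raise DomainError(f"level must be in 1..4, got {lvl}")
    uni = set(universe) if universe is not None else set(aset.universe)
    inp = compute_overlap(raw_genes, uni, aliases=aliases)
    M, N = inp.M, inp.N
    results = []
    for lvl in levels:
        names = aset.categories_at_level(lvl)
        thresh = bonferroni_threshold(alpha, len(names)) if names else alpha
        for name in names:
            genes = aset.genes_in_category(lvl, name) & uni
            n = len(genes)
            if n == 0:  # category fully outside the chosen universe
                continue
            in_hits = sorted(genes & inp.hits)
            k = len(in_hits)
            pe = enrichment_pvalue(M, n, N, k)
            pd_ = depletion_pvalue(M, n, N, k)
            results.append(
                PEAResult(
                    level=lvl, category=name, n=n, k=k, score=k / n,
                    p_enrich=pe, p_deplete=pd_, genes_in_hits=tuple(in_hits),
                    bonferroni_pass=min(pe, pd_) < thresh,
                )
            )
    return PEATable(inputs=inp, results=results, alpha=alpha, universe_source=universe_source)


# ---------------------------------------------------------------------------
# Output writers

_TSV_COLUMNS = ["level", "category", "n", "k", "score", "p_enrich", "p_deplete",
                "bonferroni_pass", "category_genes_in_hits"]


def _fmt_score(x: float) -> str:
    return f"{x:.6g}"


def _fmt_p(x: float) -> str:
    return f"{x:.6e}"


def write_pea_outputs(table: PEATable, out_dir) -> dict[str, str]:
    """Write ``results.tsv`` and a color-coded ``results.html`` into out_dir.

    Row order is deterministic (level asc, p_enrich asc, category asc).
    Returns the written paths keyed by format.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    tsv_path = os.path.join(out_dir, "results.tsv")
    html_path = os.path.join(out_dir, "results.html")
    rows = table.sorted_results()
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join([
                str(r.level), r.category, str(r.n), str(r.k), _fmt_score(r.score),
                _fmt_p(r.p_enrich), _fmt_p(r.p_deplete),
                "yes" if r.bonferroni_pass else "no",
                ",".join(r.genes_in_hits),
            ]) + "\n")
    with open(html_path, "w", encoding="utf-8") as fh:
        fh.write(render_html_report(table))
    return {"tsv": tsv_path, "html": html_path}


def _ramp(p: float, base: str) -> str:
    """Map a p-value to a white->color ramp on -log10(p), saturating at 10."""
    if p <= 0:
        s = 1.0
    else:
        s = min(-math.log10(p), 10.0) / 10.0
    lo = 255
    if base == "red":
        r, g, b = 255, round(lo * (1 - s)), round(lo * (1 - s))
    else:  # blue
        r, g, b = round(lo * (1 - s)), round(lo * (1 - s)), 255
    return f"#{r:02x}{g:02x}{b:02x}"


def render_html_report(table: PEATable) -> str:
    """XHTML report mirroring the interactive color-coded PEA view:
    enrichment cells on a white-to-red ramp, depletion on white-to-blue,
    both scaled by -log10(p) saturating at 10."""
    rows_html = []
    for r in table.sorted_results():
        rows_html.append(
            "<tr>"
            f"<td>{r.level}</td><td>{_escape(r.category)}</td>"
            f"<td>{r.n}</td><td>{r.k}</td><td>{_fmt_score(r.score)}</td>"
            f'<td style="background-color:{_ramp(r.p_enrich, "red")}">{_fmt_p(r.p_enrich)}</td>'
            f'<td style="background-color:{_ramp(r.p_deplete, "blue")}">{_fmt_p(r.p_deplete)}</td>'
            f"<td>{'yes' if r.bonferroni_pass else 'no'}</td>"
            "</tr>"
        )
    inp = table.inputs
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<html xmlns="http://www.w3.org/1999/xhtml"><head>'
        "<title>Pathway enrichment analysis</title></head><body>"
        f"<p>Universe M = {inp.M}; metabolic hits N = {inp.N}; "
        f"unmatched input tokens: {len(inp.unmatched)}; alpha = {table.alpha} "
        "(Bonferroni column is advisory; stored p-values are uncorrected).</p>"
        "<table border=\"1\"><thead><tr>"
        "<th>level</th><th>category</th><th>n</th><th>k</th><th>score</th>"
        "<th>p_enrich</th><th>p_deplete</th><th>Bonferroni</th>"
        "</tr></thead><tbody>"
        + "".join(rows_html)
        + "</tbody></table></body></html>\n"
    )


def _escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def read_gene_list(path) -> list[str]:
    """Read a plain-text gene list: one token per line, '#' comments ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out
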