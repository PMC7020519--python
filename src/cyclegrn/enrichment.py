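"""Exact-test enrichment with Benjamini-Hochberg correction.

Used both for GO-term over-representation among important TFs and for the
known-regulator enrichment check. Tests are one-sided (enrichment) by
default; the universe for a TF enrichment is the feature set of the model
under test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d) with a = in-set ∩ annotated."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def rows(self):
        return [[self.a, self.b], [self.c, self.d]]


@dataclass
class EnrichmentResult:
    term: str
    table: ContingencyTable2x2
    odds_ratio: float
    p: float
    p_adjusted: float
    significant: bool


def fisher_exact(table: ContingencyTable2x2,
                 sidedness: str = "greater") -> float:
    """Fisher's exact test p-value; one-sided enrichment by default."""
    if (table.a + table.b == 0 or table.c + table.d == 0
            or table.a + table.c == 0 or table.b + table.d == 0):
        raise ValueError("a zero margin leaves the test undefined")
    if sidedness not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    _, p = stats.fisher_exact(table.rows, alternative=sidedness)
    return float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def go_enrichment(gene_set: set[str], universe: set[str],
                  annotations: dict[str, set[str]] | pd.DataFrame,
                  alpha: float = 0.05) -> list[EnrichmentResult]:
    """Per-term enrichment of ``gene_set`` within ``universe``.

    ``annotations`` maps gene → set of terms (or is a 2-column frame of
    gene/term pairs). One test per term with ≥ 1 annotated gene in the
    universe; BH correction across all tested terms.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if isinstance(annotations, pd.DataFrame):
        ann: dict[str, set[str]] = {}
        for g, t in annotations.itertuples(index=False):
            ann.setdefault(str(g), set()).add(str(t))
        annotations = ann
    if not annotations:
        raise ValueError("empty annotation map")

    term_genes: dict[str, set[str]] = {}
    for g, terms in annotations.items():
        if g in universe:
            for t in terms:
                term_genes.setdefault(t, set()).add(g)
    results = []
    for term in sorted(term_genes):
        annotated = term_genes[term]
        a = len(gene_set & annotated)
        b = len(gene_set - annotated)
        c = len(annotated - gene_set)
        d = len(universe) - a - b - c
        table = ContingencyTable2x2(a, b, c, d)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        degenerate = (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0)
        # a degenerate margin (e.g. the set is the whole universe) carries
        # no enrichment signal: p = 1 by convention
        p = 1.0 if degenerate else fisher_exact(table, "greater")
        results.append(EnrichmentResult(term=term, table=table,
                                        odds_ratio=odds, p=p,
                                        p_adjusted=np.nan, significant=False))
    adj = bh_adjust([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
        r.significant = q <= alpha
    return results


def read_annotations(path) -> dict[str, set[str]]:
    """2-column TSV (gene, term), one pair per line."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"],
                     dtype=str, comment="#")
    ann: dict[str, set[str]] = {}
    for g, t in df.itertuples(index=False):
        ann.setdefault(g, set()).add(t)
    return ann
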