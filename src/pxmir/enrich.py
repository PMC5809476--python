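"""Hypergeometric over-representation of terms among target genes.

For a term annotated on K of N background genes, with k hits in a target
set of n genes, the enrichment p-value is the upper tail
P(X >= k), X ~ Hypergeometric(N, K, n).  Correction is Bonferroni by
default (Benjamini-Hochberg selectable); significance at corrected
p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrich",
    "correct_terms",
    "classification_table",
]

ENRICH_ALPHA = 0.05


@dataclass
class EnrichmentResult:
    term: str
    name: str
    category: str
    k: int   # target genes with the term
    K: int   # background genes with the term
    n: int   # target-set size
    N: int   # background size
    p_value: float
    p_corrected: float = float("nan")


def load_term_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id", "term_name", "category"}
    if not required <= set(df.columns):
        raise ValueError(f"term map must have columns {sorted(required)}")
    return df


def hypergeom_enrich(target_genes, background_genes,
                     term_map: pd.DataFrame) -> list[EnrichmentResult]:
    """One upper-tail hypergeometric test per term with at least one target
    hit.  ``term_map`` columns: gene_id, term_id, term_name, category."""
    target = set(target_genes)
    background = set(background_genes)
    stray = sorted(target - background)
    if stray:
        raise ValueError(f"target genes absent from background: {stray}")
    N, n = len(background), len(target)
    results = []
    grouped = term_map[term_map["gene_id"].isin(background)].groupby(
        ["term_id", "term_name", "category"])["gene_id"]
    for (term_id, term_name, category), genes in grouped:
        gset = set(genes)
        K = len(gset)
        k = len(gset & target)
        if k == 0:
            continue
        # P(X >= k) = survival function at k-1
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term_id, term_name, category,
                                        k, K, n, N, min(p, 1.0)))
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def correct_terms(results: list[EnrichmentResult],
                  method: str = "bonferroni") -> list[EnrichmentResult]:
    """Attach corrected p-values in place (and return the list)."""
    if method not in ("bonferroni", "benjamini_hochberg"):
        raise ValueError(f"unknown correction method {method!r}")
    if not results:
        return results
    ps = [r.p_value for r in results]
    sm_method = "bonferroni" if method == "bonferroni" else "fdr_bh"
    _, corrected, _, _ = multipletests(ps, method=sm_method)
    for r, pc in zip(results, corrected):
        r.p_corrected = float(pc)
    return results


def significant(results: list[EnrichmentResult],
                alpha: float = ENRICH_ALPHA) -> list[EnrichmentResult]:
    return [r for r in results if r.p_corrected <= alpha]


def classification_table(target_genes, term_map: pd.DataFrame,
                         ) -> pd.DataFrame:
    """Per-category gene counts among the target set (a gene may appear in
    several categories but counts once per category), sorted descending."""
    target = set(target_genes)
    sub = term_map[term_map["gene_id"].isin(target)]
    counts = (sub.drop_duplicates(["gene_id", "category"])
              .groupby("category")["gene_id"].count()
              .sort_values(ascending=False))
    return counts.rename("n_genes").reset_index()
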