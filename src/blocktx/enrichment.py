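"""Term over-representation of gene sets: Fisher's exact test + BH FDR.

Designed around flat, GO-Slim-style annotation: gene -> set of terms, with
an optional term -> broad-category recoding table for summary heatmaps.
The enrichment universe defaults to the genes of the analyzed matrix, not
the whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationTable",
    "read_annotation",
    "read_category_map",
    "fisher_over_representation",
    "bh_adjust",
    "enrich_sets",
    "recode_terms",
]


@dataclass
class AnnotationTable:
    """gene -> terms map with inverse view and optional broad categories."""

    gene_to_terms: dict[str, frozenset]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_to_terms = {
            g: frozenset(t) for g, t in self.gene_to_terms.items() if t
        }

    @property
    def term_to_genes(self) -> dict[str, frozenset]:
        inv: dict[str, set] = {}
        for g, terms in self.gene_to_terms.items():
            for t in terms:
                inv.setdefault(t, set()).add(g)
        return {t: frozenset(g) for t, g in inv.items()}

    @property
    def terms(self) -> frozenset:
        out: set = set()
        for t in self.gene_to_terms.values():
            out |= t
        return frozenset(out)

    @classmethod
    def from_pairs(cls, pairs, categories=None) -> "AnnotationTable":
        fwd: dict[str, set] = {}
        for gene, term in pairs:
            fwd.setdefault(gene, set()).add(term)
        return cls(
            gene_to_terms={g: frozenset(t) for g, t in fwd.items()},
            categories=dict(categories or {}),
        )


def read_annotation(path, category_path=None) -> AnnotationTable:
    """Long-format 2-column TSV (gene, term), optional (term, category) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    gene_col, term_col = df.columns[:2]
    categories = read_category_map(category_path) if category_path else {}
    return AnnotationTable.from_pairs(zip(df[gene_col], df[term_col]), categories)


def read_category_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    term_col, cat_col = df.columns[:2]
    return dict(zip(df[term_col], df[cat_col]))


def fisher_over_representation(query, universe, annotation: AnnotationTable, term):
    """One-sided Fisher (hypergeometric tail) over-representation test.

    Returns ``(odds_ratio, p)`` for the 2x2 table of query/term membership
    within the universe.  The p-value is the exact upper hypergeometric
    tail P(X >= observed overlap).  The odds ratio gets a 0.5 continuity
    correction only when a cell is zero (display convention).
    """
    query = frozenset(query)
    universe = frozenset(universe)
    if not query <= universe:
        raise ValueError("query set is not contained in the universe")
    term_genes = annotation.term_to_genes.get(term, frozenset()) & universe
    if not term_genes:
        raise ValueError(f"term {term!r} has no members in the universe")
    a = len(query & term_genes)
    b = len(query) - a
    c = len(term_genes) - a
    d = len(universe) - len(query) - c
    p = float(stats.hypergeom.sf(a - 1, len(universe), len(term_genes), len(query)))
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_sets(
    gene_sets,
    universe,
    annotation: AnnotationTable,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Over-representation of every term in every query set.

    Parameters
    ----------
    gene_sets : mapping
        set id -> iterable of gene ids (e.g. BTRs or consistency sets).
    universe : iterable
        Enrichment universe (typically the matrix's RNA ids).
    annotation : AnnotationTable
    min_term_size : int
        Terms with fewer members in the universe are not tested.

    Returns
    -------
    DataFrame with columns set_id, term, counts (a,b,c,d), odds_ratio,
    p_raw and BH-adjusted p (adjusted within each query set's family).
    """
    universe = frozenset(universe)
    t2g = {
        t: genes & universe
        for t, genes in annotation.term_to_genes.items()
    }
    testable = sorted(t for t, g in t2g.items() if len(g) >= min_term_size)
    records = []
    for sid, members in dict(gene_sets).items():
        query = frozenset(members) & universe
        for term in testable:
            tg = t2g[term]
            a = len(query & tg)
            bq = len(query) - a
            c = len(tg) - a
            d = len(universe) - len(query) - c
            p = float(stats.hypergeom.sf(a - 1, len(universe), len(tg), len(query)))
            if min(a, bq, c, d) == 0:
                odds = ((a + 0.5) * (d + 0.5)) / ((bq + 0.5) * (c + 0.5))
            else:
                odds = (a * d) / (bq * c)
            records.append(
                dict(set_id=sid, term=term, a=a, b=bq, c=c, d=d,
                     odds_ratio=float(odds), p_raw=min(p, 1.0))
            )
    result = pd.DataFrame.from_records(
        records,
        columns=["set_id", "term", "a", "b", "c", "d", "odds_ratio", "p_raw"],
    )
    result["p_adjusted"] = np.nan
    for sid, idx in result.groupby("set_id").groups.items():
        result.loc[idx, "p_adjusted"] = bh_adjust(result.loc[idx, "p_raw"])
    return result


def recode_terms(
    result: pd.DataFrame, category_map: dict[str, str], fdr: float = 0.05
) -> pd.DataFrame:
    """Collapse per-term enrichment to broad categories.

    Per (set, category): the best (minimum) adjusted p among member terms
    and the list of terms significant at ``fdr``.  Terms absent from the
    category map fall into ``"uncategorized"`` with a warning.
    """
    if result.empty:
        return pd.DataFrame(
            columns=["set_id", "category", "best_p_adjusted", "significant_terms"]
        )
    res = result.copy()
    unknown = sorted(set(res["term"]) - set(category_map))
    if unknown:
        warnings.warn(f"terms without a category, recoded as 'uncategorized': {unknown[:5]}")
    res["category"] = res["term"].map(lambda t: category_map.get(t, "uncategorized"))
    rows = []
    for (sid, cat), grp in res.groupby(["set_id", "category"]):
        sig = sorted(grp.loc[grp["p_adjusted"] < fdr, "term"])
        rows.append(
            dict(
                set_id=sid,
                category=cat,
                best_p_adjusted=float(grp["p_adjusted"].min()),
                significant_terms=sig,
            )
        )
    return pd.DataFrame(rows)
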