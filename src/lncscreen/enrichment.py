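"""Term enrichment: fold enrichment, hypergeometric p-values and BH FDR.

Contingency semantics follow DAVID: for a category, PT is the number of
background genes with at least one annotation in that category, PH the
background genes annotated to the term, LT the list genes with at least one
annotation in the category, and LH the list genes annotated to the term.
Fold enrichment is (LH/LT)/(PH/PT).  The p-value is the one-sided upper
hypergeometric tail, by default in the conservative EASE form (LH reduced by
one).  FDR is Benjamini–Hochberg, adjusted within each category family.
The screen's significance filter is fold >= 2.0 and FDR <= 0.05, both
inclusive.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import AnnotationCatalog, EnrichmentRow

logger = logging.getLogger(__name__)


def build_contingency(
    gene_list: Iterable[str], catalog: AnnotationCatalog, category: str, term: str
) -> tuple[int, int, int, int]:
    """(LH, LT, PH, PT) for one term; gene symbols are case-insensitive."""
    terms = catalog.categories[category]
    term_genes = terms[term]
    annotated = frozenset().union(*terms.values())
    genes = {g.upper() for g in gene_list} & catalog.background
    lt_genes = genes & annotated
    return (
        len(lt_genes & term_genes),
        len(lt_genes),
        len(term_genes),
        len(annotated),
    )


def fold_enrichment(lh: int, lt: int, ph: int, pt: int) -> float:
    """(LH/LT) / (PH/PT), the DAVID fold-enrichment statistic."""
    if lt <= 0 or ph <= 0 or pt <= 0:
        raise ValueError(f"LT, PH, PT must be positive, got LT={lt} PH={ph} PT={pt}")
    return (lh / lt) / (ph / pt)


def enrichment_pvalue(lh, lt: int, ph: int, pt: int, ease: bool = True):
    """One-sided upper-tail hypergeometric p-value.

    P(X >= LH) for X ~ Hypergeom(PT, PH, LT); with ``ease=True`` (DAVID's
    EASE score) LH is replaced by max(LH − 1, 0), which is never
    anti-conservative relative to the exact tail.  ``lh`` may be an array of
    hit counts for the same (LT, PH, PT), returning an array.
    """
    lh_arr = np.asarray(lh, dtype=int)
    if not (0 < pt and 0 <= lt <= pt and 0 <= ph <= pt):
        raise ValueError(f"invalid contingency LT={lt} PH={ph} PT={pt}")
    if np.any(lh_arr < 0) or np.any(lh_arr > min(lt, ph)):
        raise ValueError(f"invalid contingency LH={lh} LT={lt} PH={ph} PT={pt}")
    x = np.maximum(lh_arr - 1, 0) if ease else lh_arr
    # sf(x-1) = P(X >= x)
    p = np.minimum(1.0, hypergeom.sf(x - 1, pt, ph, lt))
    return float(p) if lh_arr.ndim == 0 else p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    gene_list: Iterable[str], catalog: AnnotationCatalog, ease: bool = True
) -> list[EnrichmentRow]:
    """Score every term; FDR adjusted within each category family.

    Terms with LT = 0 or PH = 0 have an undefined fold enrichment and are
    skipped with a log entry.
    """
    genes = {g.upper() for g in gene_list}
    rows: list[EnrichmentRow] = []
    for category in sorted(catalog.categories):
        cat_rows: list[EnrichmentRow] = []
        for term in sorted(catalog.categories[category]):
            lh, lt, ph, pt = build_contingency(genes, catalog, category, term)
            if lt == 0 or ph == 0:
                logger.info("term %r in %r skipped (LT=%d, PH=%d)", term, category, lt, ph)
                continue
            cat_rows.append(
                EnrichmentRow(
                    category=category,
                    term=term,
                    lh=lh,
                    lt=lt,
                    ph=ph,
                    pt=pt,
                    fold=fold_enrichment(lh, lt, ph, pt),
                    p=enrichment_pvalue(lh, lt, ph, pt, ease=ease),
                )
            )
        if cat_rows:
            q = bh_fdr([r.p for r in cat_rows])
            for r, fdr in zip(cat_rows, q):
                r.fdr = float(fdr)
        rows.extend(cat_rows)
    return rows


def filter_enriched(
    rows: Iterable[EnrichmentRow], min_fold: float = 2.0, max_fdr: float = 0.05
) -> list[EnrichmentRow]:
    """Keep rows with fold >= min_fold and FDR <= max_fdr (both inclusive),
    sorted by fold enrichment descending."""
    kept = [r for r in rows if r.fold >= min_fold and r.fdr <= max_fdr]
    return sorted(kept, key=lambda r: (-r.fold, r.category, r.term))
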