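"""Contingency building, fold enrichment, hypergeometric tail and BH FDR."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from lncscreen.containers import AnnotationCatalog, EnrichmentRow
from lncscreen.enrichment import (
    bh_fdr,
    build_contingency,
    enrich,
    enrichment_pvalue,
    filter_enriched,
    fold_enrichment,
)

#: Reference rows from a DAVID-style functional report: (category, term,
#: LH, LT, PH, PT, fold at the printed precision).
REFERENCE_FOLDS = [
    ("UP_KW_PTM", "Isopeptide bond", 19, 70, 1569, 13044, 2.257),
    ("GOTERM_CC_DIRECT", "Nucleoplasm", 29, 79, 3674, 21301, 2.128),
    ("INTERPRO", "SNF2-related", 7, 273, 34, 20806, 15.69),
    ("UP_SEQ_FEATURE", "Ion transport", 7, 280, 56, 22228, 9.923),
    ("UP_SEQ_FEATURE", "Helicase ATP-binding", 9, 280, 117, 22228, 6.107),
    ("INTERPRO", "Immunoglobulin I-set", 12, 273, 150, 20806, 6.097),
    ("GOTERM_CC_DIRECT", "Sarcolemma", 11, 277, 141, 21301, 5.999),
    ("UP_KW_MOLECULAR_FUNCTION", "Helicase", 9, 168, 139, 12161, 4.687),
    ("GOTERM_CC_DIRECT", "Postsynaptic density", 19, 277, 375, 21301, 3.896),
    ("UP_KW_MOLECULAR_FUNCTION", "Chromatin regulator", 13, 168, 299, 12161, 3.147),
    ("GOTERM_CC_DIRECT", "Axon", 21, 277, 516, 21301, 3.130),
    ("GOTERM_CC_DIRECT", "Neuronal cell body", 26, 277, 659, 21301, 3.034),
    ("GOTERM_CC_DIRECT", "Dendrite", 24, 277, 626, 21301, 2.948),
    ("UP_SEQ_FEATURE", "Basic residues", 24, 280, 669, 22228, 2.848),
    ("GOTERM_CC_DIRECT", "Neuron projection", 21, 277, 582, 21301, 2.775),
    ("UP_KW_CELLULAR_COMPONENT", "Synapse", 20, 253, 520, 17987, 2.734),
    ("UP_SEQ_FEATURE", "Acidic residues", 29, 280, 956, 22228, 2.408),
    ("GOTERM_CC_DIRECT", "Glutamatergic synapse", 20, 277, 663, 21301, 2.320),
    ("GOTERM_CC_DIRECT", "Cell projection", 37, 277, 1246, 21301, 2.284),
    ("GOTERM_CC_DIRECT", "Synapse", 30, 277, 1019, 21301, 2.264),
    ("GOTERM_CC_DIRECT", "Perinuclear region of cytoplasm", 24, 277, 842, 21301, 2.192),
    ("GOTERM_CC_DIRECT", "Macromolecular complex", 26, 277, 946, 21301, 2.114),
    ("UP_SEQ_FEATURE", "Basic and acidic residues", 139, 280, 5402, 22228, 2.043),
    ("UP_KW_CELLULAR_COMPONENT", "Cell projection", 34, 253, 1205, 17987, 2.006),
]


def hypergeom_tail_oracle(lh, lt, ph, pt):
    """Exact P(X >= lh) by factorial enumeration, in rational arithmetic."""
    total = comb(pt, lt)
    acc = Fraction(0)
    for x in range(lh, min(lt, ph) + 1):
        acc += Fraction(comb(ph, x) * comb(pt - ph, lt - x), total)
    return float(acc)


class TestFoldEnrichment:
    @pytest.mark.parametrize("cat,term,lh,lt,ph,pt,expected", REFERENCE_FOLDS)
    def test_reference_rows_to_printed_precision(self, cat, term, lh, lt, ph, pt, expected):
        decimals = len(str(expected).split(".")[1])
        assert round(fold_enrichment(lh, lt, ph, pt), decimals) == expected

    def test_equal_proportions_give_fold_one(self):
        assert fold_enrichment(5, 50, 100, 1000) == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(1, 0, 5, 10)


class TestPvalue:
    def test_lh_zero_without_ease_is_one(self):
        assert enrichment_pvalue(0, 10, 5, 20, ease=False) == 1.0

    def test_matches_factorial_oracle(self):
        assert enrichment_pvalue(3, 10, 5, 20, ease=False) == pytest.approx(
            hypergeom_tail_oracle(3, 10, 5, 20), abs=1e-14
        )

    def test_ease_with_lh_one_equals_tail_at_zero(self):
        assert enrichment_pvalue(1, 10, 5, 20, ease=True) == 1.0

    def test_ease_never_smaller_than_exact_tail(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            pt = int(rng.integers(5, 40))
            ph = int(rng.integers(1, pt + 1))
            lt = int(rng.integers(1, pt + 1))
            lh = int(rng.integers(max(0, lt + ph - pt), min(lt, ph) + 1))
            assert enrichment_pvalue(lh, lt, ph, pt, ease=True) >= enrichment_pvalue(
                lh, lt, ph, pt, ease=False
            ) - 1e-15

    def test_invalid_contingency_rejected(self):
        with pytest.raises(ValueError):
            enrichment_pvalue(6, 5, 5, 20)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        # q_i = min over j>=i of p_(j) * m / j = 0.04 for every rank here
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(29)
        p = rng.uniform(size=30)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_term_order_permutation_invariance(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))


def toy_catalog():
    background = [f"g{i}" for i in range(40)]
    return AnnotationCatalog(
        categories={
            "CAT": {
                "term_a": frozenset(f"G{i}" for i in range(10)),
                "term_b": frozenset(f"G{i}" for i in range(5, 30)),
            }
        },
        background=frozenset(background),
    )


class TestContingency:
    def test_list_equal_background_gives_fold_one(self):
        cat = toy_catalog()
        for term in cat.categories["CAT"]:
            lh, lt, ph, pt = build_contingency(cat.background, cat, "CAT", term)
            assert (lh, lt) == (ph, pt)
            assert fold_enrichment(lh, lt, ph, pt) == pytest.approx(1.0)

    def test_gene_outside_category_excluded_from_lt(self):
        cat = toy_catalog()
        # g35..g39 are in the background but not annotated in CAT
        lh, lt, ph, pt = build_contingency(["g0", "g35"], cat, "CAT", "term_a")
        assert (lh, lt) == (1, 1)
        assert pt == 30  # union of term_a and term_b annotations

    def test_case_insensitive_symbols(self):
        cat = toy_catalog()
        lh, _, _, _ = build_contingency(["G0", "g1"], cat, "CAT", "term_a")
        assert lh == 2

    def test_planted_term_counts(self, planted_run):
        _, _, results = planted_run
        truth = results["truth"]
        for idx, (rows, kept) in results["enrichment"].items():
            motif_i = idx - 1  # runs are 1-indexed, planted motifs 0-indexed
            planted_genes = truth.planted_target_genes[motif_i]
            for r in rows:
                if r.term.startswith(f"TERM_PLANTED_M{motif_i + 1}_"):
                    assert r.lh == len(planted_genes)


class TestFilterEnriched:
    def _row(self, fold, fdr):
        return EnrichmentRow("C", f"t{fold}{fdr}", 1, 2, 3, 4, fold, 0.01, fdr)

    def test_inclusive_boundaries(self):
        kept = filter_enriched([self._row(2.0, 0.05)])
        assert len(kept) == 1

    def test_fold_below_threshold_dropped(self):
        assert filter_enriched([self._row(1.99, 0.001)]) == []

    def test_sorted_by_fold_descending(self):
        rows = [self._row(2.5, 0.01), self._row(4.0, 0.01), self._row(3.0, 0.01)]
        assert [r.fold for r in filter_enriched(rows)] == [4.0, 3.0, 2.5]


class TestEnrich:
    def test_planted_terms_recovered_exactly(self, planted_run):
        _, _, results = planted_run
        truth = results["truth"]
        assert results["enriched_terms"] == truth.enriched_terms

    def test_null_calibration_over_twenty_seeds(self):
        """Without planted signal, the fold/FDR filter should fire in at
        most one of twenty random gene lists."""
        from lncscreen.containers import SyntheticTruth
        from lncscreen.synthetic import generate_mrna_db

        false_positive_runs = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            truth = SyntheticTruth(
                probe_ids=["p0"],
                suppressive_probe_ids=set(),
                planted_motifs=[("UUCUUUCACAUA", 0)],
                seed=seed,
            )
            db = generate_mrna_db(
                truth, n_decoys=120, n_targets_per_motif=2, plant_terms=False,
                n_background_terms=25,
            )
            genes = [t.gene_symbol for t in db.transcripts]
            gene_list = rng.choice(genes, size=15, replace=False)
            catalog = AnnotationCatalog(
                categories={"SYNTH_DB": {t: g for t, (_, g) in db.gmt.items()}},
                background=frozenset(genes),
            )
            kept = filter_enriched(enrich(gene_list, catalog))
            if kept:
                false_positive_runs += 1
        assert false_positive_runs <= 1
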