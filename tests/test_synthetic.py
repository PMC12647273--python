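"""The generator's contracts: shapes, planted signal, determinism."""

import numpy as np
import pandas as pd
import pytest

from lncscreen import preprocess as pp
from lncscreen import pca
from lncscreen.consensus import extract_common_sequences, reverse_complement
from lncscreen.matching import scan_database
from lncscreen.synthetic import (
    generate_expression,
    generate_mrna_db,
    generate_probe_sequences,
)


class TestGenerateExpression:
    def test_shape_contract(self):
        m, truth = generate_expression(n_probes=1000, n_suppressive=50, seed=7)
        assert m.intensities.shape == (1000, 8)
        assert len(truth.suppressive_probe_ids) == 50
        assert truth.suppressive_probe_ids <= set(m.probe_ids)
        assert set(m.condition.value_counts()) == {2}
        assert (m.intensities > 0).all().all()
        assert m.confidence.isin([0, 1, 2]).all().all()

    def test_suppressive_means_decrease_with_severity(self):
        m, truth = generate_expression(
            n_probes=400, n_suppressive=80, seed=3, noise_sd=10.0, effect_size=150.0
        )
        sup = m.intensities.loc[sorted(truth.suppressive_probe_ids)]
        by_cond = sup.T.groupby(m.condition).mean().mean(axis=1)
        assert (
            by_cond["control"] > by_cond["weak"] > by_cond["moderate"] > by_cond["severe"]
        )
        bg = m.intensities.drop(index=sorted(truth.suppressive_probe_ids))
        bg_lnc = bg[m.biotype.loc[bg.index] == "lncRNA"]
        bg_cond = bg_lnc.T.groupby(m.condition).median().median(axis=1)
        assert bg_cond.max() / bg_cond.min() < 1.05  # severity-independent

    def test_null_effect_recovery_no_better_than_chance(self):
        m, truth = generate_expression(
            n_probes=300, n_suppressive=30, effect_size=0.0, seed=13
        )
        z, filtered, _ = pp.run_preprocess(m)
        p = pca.run_pca(z)
        sel = pca.top_k(p, pca.select_component(p, m.severity()), k=30)
        recovered = len(set(sel.selected_probe_ids) & truth.suppressive_probe_ids)
        # chance alone: hypergeometric mean ~ 30*30/n_kept; demand no signal
        assert recovered <= 10

    def test_planted_recovery_after_preprocess_pca_chain(self):
        m, truth = generate_expression(
            n_probes=500, n_suppressive=25, effect_size=250.0, noise_sd=50.0, seed=11
        )
        z, _, _ = pp.run_preprocess(m)
        p = pca.run_pca(z)
        sel = pca.top_k(p, pca.select_component(p, m.severity()), k=25)
        frac = len(set(sel.selected_probe_ids) & truth.suppressive_probe_ids) / 25
        assert frac >= 0.9

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_probes=0), "n_probes"),
            (dict(n_suppressive=0), "n_suppressive"),
            (dict(n_suppressive=2000), "n_suppressive"),
            (dict(noise_sd=-1.0), "noise_sd"),
            (dict(base_intensity=0.0), "base_intensity"),
        ],
    )
    def test_bad_parameters_named(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            generate_expression(**{**dict(n_probes=100, n_suppressive=10), **kwargs})

    def test_determinism_same_seed_identical(self):
        a, _ = generate_expression(n_probes=150, n_suppressive=15, seed=21)
        b, _ = generate_expression(n_probes=150, n_suppressive=15, seed=21)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)
        pd.testing.assert_frame_equal(a.confidence, b.confidence)
        c, _ = generate_expression(n_probes=150, n_suppressive=15, seed=22)
        assert not a.intensities.equals(c.intensities)


class TestGenerateProbeSequences:
    def _truth(self, seed=7, motifs=None):
        _, truth = generate_expression(
            n_probes=60, n_suppressive=10, seed=seed, planted_motifs=motifs
        )
        return truth

    def test_zero_corruption_motifs_verbatim(self):
        truth = self._truth()
        aln = generate_probe_sequences(truth, probe_length=60, corruption=0.0)
        seqs = dict(zip(aln.ids, aln.sequences))
        for pid in truth.suppressive_probe_ids:
            for motif, col in truth.planted_motifs:
                assert seqs[pid][col : col + len(motif)] == motif

    def test_planted_column_run_recovered_downstream(self):
        truth = self._truth(motifs=[("AUCAUCUUUCC", 20)])
        aln = generate_probe_sequences(truth, probe_length=60, corruption=0.0)
        sub = aln.subset(sorted(truth.suppressive_probe_ids))
        runs = extract_common_sequences(sub, min_frac=0.9)
        assert any(r.start_col <= 20 and r.end_col >= 31 for r in runs)
        assert any("AUCAUCUUUCC" in r.sequence for r in runs)

    def test_heavy_corruption_kills_extraction_at_high_threshold(self):
        truth = self._truth(seed=9)
        aln = generate_probe_sequences(truth, probe_length=60, corruption=0.5, seed=9)
        sub = aln.subset(sorted(truth.suppressive_probe_ids))
        runs = extract_common_sequences(sub, min_frac=0.9)
        assert runs == []

    def test_motif_exceeding_probe_bounds_rejected(self):
        truth = self._truth(motifs=[("AUCAUCUUUCC", 55)])
        with pytest.raises(ValueError, match="exceeds"):
            generate_probe_sequences(truth, probe_length=60)

    def test_gapless_equal_length(self):
        truth = self._truth()
        aln = generate_probe_sequences(truth, probe_length=50)
        assert all(len(s) == 50 and "-" not in s for s in aln.sequences)


class TestGenerateMrnaDb:
    def test_planted_occurrences_found_and_decoys_clean(self):
        _, truth = generate_expression(n_probes=40, n_suppressive=8, seed=5)
        db = generate_mrna_db(truth, n_decoys=60, n_targets_per_motif=6)
        by_id = {t.transcript_id: t for t in db.transcripts}
        for mi, (motif, _) in enumerate(truth.planted_motifs):
            comp = reverse_complement(motif)
            for tid in truth.planted_target_transcripts[mi]:
                hits = scan_database(comp, [by_id[tid]], min_identity=0.85)
                assert hits, f"planted occurrence missing in {tid}"
            decoys = [t for t in db.transcripts if t.transcript_id.startswith("TX_D")]
            assert all(not scan_database(comp, [d], 0.85) for d in decoys)

    def test_header_fractions_and_whitelist_coverage(self):
        _, truth = generate_expression(n_probes=40, n_suppressive=8, seed=5)
        db = generate_mrna_db(truth, n_decoys=100, predicted_frac=0.4)
        decoys = [t for t in db.transcripts if t.transcript_id.startswith("TX_D")]
        flagged = [t for t in decoys if "PREDICTED" in t.description or "cDNA" in t.description]
        assert 20 <= len(flagged) <= 60
        for genes in truth.planted_target_genes.values():
            assert {g.upper() for g in genes} <= db.whitelist

    def test_truth_terms_planted_over_target_genes(self):
        _, truth = generate_expression(n_probes=40, n_suppressive=8, seed=5)
        db = generate_mrna_db(truth, n_decoys=50)
        assert truth.enriched_terms
        for term in truth.enriched_terms:
            _, genes = db.gmt[term]
            mi = int(term.split("_M")[1].split("_")[0]) - 1
            assert {g.upper() for g in truth.planted_target_genes[mi]} <= genes
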