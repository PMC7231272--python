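"""Synthetic-data generators: determinism, planted truth, planted effects."""

import numpy as np
import pandas as pd
import pytest

from promotif import (ExpressionModule, SimConfig, conservation_matrix,
                      gen_background_promoters, gen_ct_table,
                      gen_expression_matrix, gen_ortholog_promoters,
                      plant_motifs, scan, simulate_enrichment_study, spawn_seeds)
from promotif.simulate import random_pwm


class TestBackgroundPromoters:
    def test_degenerate_composition(self):
        pset = gen_background_promoters(1, 10, composition=(1, 0, 0, 0), seed=0)
        assert pset.sequences == ["AAAAAAAAAA"]

    def test_law_of_large_numbers(self):
        pset = gen_background_promoters(10_000, 100, seed=3)
        joined = "".join(pset.sequences)
        for base in "ACGT":
            assert abs(joined.count(base) / len(joined) - 0.25) < 0.01

    def test_skewed_composition(self):
        comp = (0.1, 0.2, 0.3, 0.4)
        pset = gen_background_promoters(2_000, 200, composition=comp, seed=9)
        joined = "".join(pset.sequences)
        for base, p in zip("ACGT", comp):
            assert abs(joined.count(base) / len(joined) - p) < 0.01

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            gen_background_promoters(5, 10, composition=(0.5, 0.5, 0.5, 0.5), seed=0)

    def test_deterministic_given_seed(self):
        a = gen_background_promoters(50, 120, seed=7)
        b = gen_background_promoters(50, 120, seed=7)
        assert a.sequences == b.sequences
        assert a.sequences != gen_background_promoters(50, 120, seed=8).sequences


class TestPlanting:
    def test_zero_probability_is_identity(self, consensus_pwm):
        pset = gen_background_promoters(30, 80, seed=1)
        out, log = plant_motifs(pset, consensus_pwm, plant_probability=0.0, seed=2)
        assert out.sequences == pset.sequences
        assert len(log) == 0

    def test_consensus_planted_exactly_where_logged(self, consensus_pwm):
        from promotif._seqs import revcomp
        pset = gen_background_promoters(60, 100, seed=4)
        out, log = plant_motifs(pset, consensus_pwm, plant_probability=1.0, seed=5)
        assert len(log) == 60
        cons = consensus_pwm.consensus()
        by_id = dict(zip(out.ids, out.sequences))
        for rec in log:
            written = by_id[rec.promoter_id][rec.offset:rec.offset + len(cons)]
            assert written == (cons if rec.strand == "+" else revcomp(cons))

    def test_sites_recoverable_by_scan_at_logged_coordinates(self, consensus_pwm):
        pset = gen_background_promoters(40, 90, seed=6)
        out, log = plant_motifs(pset, consensus_pwm, plant_probability=0.7, seed=7)
        by_id = dict(zip(out.ids, out.sequences))
        for rec in log:
            hits = scan(by_id[rec.promoter_id], consensus_pwm,
                        consensus_pwm.max_score - 1e-9)
            assert (rec.offset, rec.strand) in {(h.offset, h.strand) for h in hits}

    def test_multiple_sites_never_overlap(self, consensus_pwm):
        pset = gen_background_promoters(50, 200, seed=8)
        _, log = plant_motifs(pset, consensus_pwm, plant_probability=1.0,
                              sites_per_promoter=3, seed=9)
        frame = log.to_frame()
        L = len(consensus_pwm)
        for _, grp in frame.groupby("promoter_id"):
            offs = sorted(grp["offset"])
            assert all(b - a >= L for a, b in zip(offs, offs[1:]))

    def test_strand_probability_balance(self, consensus_pwm):
        pset = gen_background_promoters(1000, 60, seed=10)
        _, log = plant_motifs(pset, consensus_pwm, plant_probability=1.0,
                              strand_probability=0.5, seed=11)
        fwd = sum(1 for r in log if r.strand == "+") / len(log)
        assert 0.45 <= fwd <= 0.55

    def test_impossible_packing_raises(self, consensus_pwm):
        pset = gen_background_promoters(5, 14, seed=1)
        with pytest.raises(RuntimeError, match="non-overlapping"):
            plant_motifs(pset, consensus_pwm, plant_probability=1.0,
                         sites_per_promoter=3, seed=2)

    def test_study_determinism(self, consensus_pwm):
        cfg = SimConfig(seed=33, n_target_promoters=20, n_reference_promoters=30,
                        promoter_length=100)
        a = simulate_enrichment_study(cfg, consensus_pwm)
        b = simulate_enrichment_study(cfg, consensus_pwm)
        assert a[0].sequences == b[0].sequences
        assert a[1].sequences == b[1].sequences
        assert a[2].to_frame().equals(b[2].to_frame())


class TestExpressionMatrix:
    conds = ["stress"] * 4 + ["control"] * 4

    def test_noiseless_block_has_exact_fold_change(self):
        mod = ExpressionModule(genes=(0, 1, 2), effects={"stress": 2.0})
        expr = gen_expression_matrix(10, self.conds, [mod], noise_sd=0.0, seed=0)
        lfc = expr.iloc[:, :4].mean(axis=1) - expr.iloc[:, 4:].mean(axis=1)
        assert np.allclose(lfc[:3], 2.0) and np.allclose(lfc[3:], 0.0)

    def test_block_genes_correlate_more_within_than_between(self):
        rng = np.random.default_rng(0)
        conds = [f"c{j}" for j in range(12)]
        eff = {c: float(rng.normal(0, 2)) for c in conds}
        mod = ExpressionModule(genes=tuple(range(30)), effects=eff)
        expr = gen_expression_matrix(100, conds, [mod], noise_sd=0.3, seed=1)
        corr = np.corrcoef(expr.to_numpy())
        within = corr[:30, :30][np.triu_indices(30, 1)].mean()
        between = corr[:30, 30:].mean()
        assert within > between

    def test_overlapping_blocks_rejected(self):
        mods = [ExpressionModule(genes=(0, 1), effects={"stress": 1.0}),
                ExpressionModule(genes=(1, 2), effects={"stress": 1.0})]
        with pytest.raises(ValueError, match="overlap"):
            gen_expression_matrix(5, self.conds, mods, seed=0)


class TestOrthologPromoters:
    species = ["sp_a", "sp_b", "sp_c", "sp_d", "sp_e"]

    def _pwms(self):
        return [random_pwm("motif_all", 12, seed=21, total_count=200, concentration=0.1),
                random_pwm("motif_some", 12, seed=22, total_count=200, concentration=0.1)]

    def test_zero_divergence_scaffolds_identical_outside_motifs(self):
        pwms = self._pwms()
        block, truth, slots = gen_ortholog_promoters(
            self.species, pwms, {"motif_all": self.species, "motif_some": []},
            seed=3, substitution_rate=0.0, deletion_rate=0.0)
        assert len(set(block.rows)) == 1  # motif_all everywhere, no divergence

    def test_presence_matrix_matches_script(self):
        pwms = self._pwms()
        thresholds = {p.matrix_id: 0.8 * p.max_score for p in pwms}
        script = {"motif_all": self.species, "motif_some": self.species[:2]}
        block, truth, _ = gen_ortholog_promoters(self.species, pwms, script, seed=4,
                                                 check_thresholds=thresholds)
        report = conservation_matrix(block, pwms, thresholds)
        pd.testing.assert_frame_equal(report.presence, truth)
        assert report.conserved_in_all["motif_all"]
        assert not report.conserved_in_all["motif_some"]

    def test_unknown_species_in_script_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            gen_ortholog_promoters(self.species, self._pwms(),
                                   {"motif_all": ["nope"]}, seed=0)


class TestCtTable:
    def test_noiseless_fold_change_shifts_ct_exactly(self):
        ct = gen_ct_table(["g", "r1"], ["stress", "control"],
                          {"g": {"stress": 4.0}}, ct_noise_sd=0.0,
                          n_replicates=3, seed=0, references=["r1"])
        g = ct[ct.gene == "g"].groupby("group")["ct"].mean()
        assert g["control"] - g["stress"] == pytest.approx(2.0)  # log2(4)

    def test_reference_fold_change_must_be_one(self):
        with pytest.raises(ValueError, match="reference gene"):
            gen_ct_table(["g", "r1"], ["stress"], {"r1": {"stress": 2.0}},
                         references=["r1"], seed=0)


def test_spawned_seeds_are_distinct_and_bounded():
    seeds = spawn_seeds(12345, 64)
    assert len(set(seeds)) == 64
    assert all(0 <= s < 2**31 for s in seeds)
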