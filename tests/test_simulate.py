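import numpy as np
import pandas as pd
import pytest

from lncm6a import (
    SimulationConfig,
    filter_expressed,
    gc_content,
    log2_transform,
    motif_count,
    pearson_r,
    simulate_cohort,
    simulate_drug_response,
    simulate_multi_cancer,
    simulate_sequences,
    simulate_survival,
)
from lncm6a.seqfeat import cpg_count


class TestConfigValidation:
    def test_rho_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(rho_signal=1.0)

    def test_overplanted_lncrnas_rejected(self):
        cfg = SimulationConfig(n_lncrnas=5, frac_related=1.0,
                               n_triple_lncrnas=3)
        with pytest.raises(ValueError, match="planted"):
            simulate_cohort(cfg)

    def test_triple_loadings_variance_guard(self):
        with pytest.raises(ValueError, match="variance"):
            SimulationConfig(
                triple_mirna_loading=0.8, triple_shared_loading=0.7
            )


class TestCohort:
    def test_same_seed_byte_identical(self, tmp_path, small_cfg):
        from lncm6a.core_io import write_expression_matrix

        paths = []
        for name in ("a.tsv", "b.tsv"):
            expr, _, _ = simulate_cohort(small_cfg)
            p = tmp_path / name
            write_expression_matrix(expr, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_planted_correlation_magnitude(self):
        cfg = SimulationConfig(
            n_samples=500, n_lncrnas=50, n_mrnas=40, n_mirnas=8,
            rho_signal=0.6, seed=5,
        )
        expr, _, truth = simulate_cohort(cfg)
        logged = log2_transform(filter_expressed(expr))
        for lnc, reg, sign in truth.related_pairs:
            if lnc in {f"LNC{cfg.n_related + k:04d}"
                       for k in range(cfg.n_triple_lncrnas)}:
                continue  # triple lncRNAs carry the weaker loading
            r, _ = pearson_r(logged.values.loc[lnc], logged.values.loc[reg])
            expected = 0.6 if sign == "positive" else -0.6
            assert r == pytest.approx(expected, abs=0.12)

    def test_frac_related_zero_empty_truth(self):
        cfg = SimulationConfig(
            n_samples=50, n_lncrnas=20, n_mrnas=20, n_mirnas=5,
            frac_related=0.0, n_triple_lncrnas=0, seed=1,
        )
        _, _, truth = simulate_cohort(cfg)
        assert truth.related_pairs == set()

    def test_emitted_files_parse_through_core_io(self, tmp_path, small_cfg):
        from lncm6a.core_io import (
            read_expression_matrix,
            read_interactions,
            write_expression_matrix,
            write_interactions,
        )

        expr, cat, _ = simulate_cohort(small_cfg)
        write_expression_matrix(expr, tmp_path / "e.tsv")
        write_interactions(cat, tmp_path / "i.tsv")
        again = read_expression_matrix(tmp_path / "e.tsv")
        assert again.values.shape == expr.values.shape
        read_interactions(tmp_path / "i.tsv")

    def test_truth_ids_exist_in_matrix(self, small_cohort):
        expr, cat, truth = small_cohort
        genes = set(expr.gene_ids)
        for l, r, _ in truth.related_pairs:
            assert l in genes and r in genes
        for l, m, g in truth.true_triples:
            assert {l, m, g} <= genes


class TestDrugResponse:
    def test_noise_free_single_gene_correlates_perfectly(self, small_logged):
        cfg = SimulationConfig(
            n_samples=300, n_lncrnas=60, n_mirnas=10, n_mrnas=80,
            n_effect_genes=1, drug_noise_sd=0.0, n_signal_drugs=1, seed=11,
        )
        from lncm6a.simulate import SyntheticTruth, triple_lncrna_ids

        truth = SyntheticTruth()
        lnc = triple_lncrna_ids(cfg)[0]
        truth.true_triples = {(lnc, "MIR000", "MRNA0000")}
        drugs = simulate_drug_response(cfg, small_logged, truth)
        gene = truth.drug_effect_genes["DRUG00"][0][0]
        r, _ = pearson_r(
            small_logged.values.loc[gene], drugs.ic50.loc["DRUG00"]
        )
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_null_drug_uncorrelated(self, small_cohort, small_logged):
        cfg = SimulationConfig(
            n_samples=300, n_lncrnas=60, n_mirnas=10, n_mrnas=80, seed=11
        )
        _, _, truth = small_cohort
        drugs = simulate_drug_response(cfg, small_logged, truth)
        null_drug = f"DRUG{cfg.n_drugs - 1:02d}"
        assert truth.drug_effect_genes[null_drug] == []
        rs = [
            pearson_r(small_logged.values.loc[g], drugs.ic50.loc[null_drug])[0]
            for g in small_logged.genes_with_role("mRNA")[:50]
        ]
        # null |r| ~ sqrt(2/(pi*n)) = 0.046 at n=300
        assert np.mean(np.abs(rs)) < 0.1

    def test_same_seed_reproducible(self, small_cohort, small_logged, small_cfg):
        _, _, truth = small_cohort
        a = simulate_drug_response(small_cfg, small_logged, truth)
        b = simulate_drug_response(small_cfg, small_logged, truth)
        pd.testing.assert_frame_equal(a.ic50, b.ic50)


class TestSurvivalSimulation:
    def test_no_censoring_all_events(self, small_cohort, small_logged):
        cfg = SimulationConfig(
            n_samples=300, n_lncrnas=60, n_mirnas=10, n_mrnas=80,
            censoring_fraction=0.0, seed=11,
        )
        _, _, truth = small_cohort
        clin = simulate_survival(cfg, small_logged, truth)
        assert (clin.table["event"] == 1).all()

    def test_censoring_fraction_approximately_hit(self, small_logged, small_cohort):
        cfg = SimulationConfig(
            n_samples=300, n_lncrnas=60, n_mirnas=10, n_mrnas=80,
            censoring_fraction=0.4, seed=11,
        )
        _, _, truth = small_cohort
        clin = simulate_survival(cfg, small_logged, truth)
        censored = 1 - clin.table["event"].mean()
        assert censored == pytest.approx(0.4, abs=0.12)

    def test_missing_planted_lncrna_rejected(self, small_logged, small_cohort):
        cfg = SimulationConfig(
            n_samples=300, n_lncrnas=60, n_mirnas=10, n_mrnas=80,
            n_survival_lncrnas=1, seed=11,
        )
        _, _, truth = small_cohort
        no_lnc = small_logged.subset_genes(
            small_logged.genes_with_role("mRNA")
        )
        with pytest.raises(ValueError, match="absent"):
            simulate_survival(cfg, no_lnc, truth)


class TestSequences:
    CFG = SimulationConfig(
        n_samples=10, n_lncrnas=20, n_mrnas=10, n_mirnas=5,
        seq_length=2000, gc_target=0.5, n_drach_planted=3, seed=3,
    )

    def test_truth_matches_recomputation_exactly(self):
        seqs, _, truth = simulate_sequences(self.CFG)
        for row in truth.itertuples():
            s = seqs[row.seq_id]
            assert gc_content(s) == row.gc
            assert cpg_count(s) == row.cpg_count
            assert motif_count(s, "DRACH") == row.drach_count

    def test_planted_motifs_are_lower_bound(self):
        seqs, _, truth = simulate_sequences(self.CFG)
        for row in truth.itertuples():
            assert row.drach_count >= row.n_planted

    def test_gc_concentrates_at_target(self):
        cfg = SimulationConfig(
            n_samples=10, n_lncrnas=4, n_mrnas=10, n_mirnas=5,
            frac_related=0.0, n_triple_lncrnas=0, cpg_enrichment=1.0,
            seq_length=10000, gc_target=0.5, seed=4,
        )
        seqs, _, _ = simulate_sequences(cfg)
        for s in seqs.values():
            assert 0.45 <= gc_content(s) <= 0.55

    def test_seed_reproducibility(self):
        a, _, _ = simulate_sequences(self.CFG)
        b, _, _ = simulate_sequences(self.CFG)
        assert a == b

    def test_motifs_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            simulate_sequences(
                SimulationConfig(seq_length=20, n_drach_planted=5)
            )

    def test_cpg_enrichment_raises_cpg_density(self):
        base = SimulationConfig(
            n_samples=10, n_lncrnas=30, n_mrnas=10, n_mirnas=5,
            seq_length=4000, cpg_enrichment=4.0, n_drach_planted=0, seed=9,
        )
        seqs, _, truth = simulate_sequences(base)
        related = truth[truth["is_related"]]["cpg_count"].mean()
        other = truth[~truth["is_related"]]["cpg_count"].mean()
        assert related > 1.25 * other
        # the boost is confined to the core window around the TSS
        lo, hi = 4000 // 2 - 800, 4000 // 2 + 800
        rel_ids = set(truth[truth["is_related"]]["seq_id"])
        core = np.mean([cpg_count(seqs[s][lo:hi]) / (hi - lo)
                        for s in rel_ids])
        flank = np.mean([cpg_count(seqs[s][:lo]) / lo for s in rel_ids])
        assert core > 1.5 * flank


class TestMultiCancer:
    def test_same_planting_different_noise(self):
        cfg = SimulationConfig(
            n_samples=60, n_cancers=2, n_lncrnas=20, n_mrnas=40, n_mirnas=5,
            seed=2,
        )
        cohorts = simulate_multi_cancer(cfg)
        (e1, _, t1), (e2, _, t2) = cohorts["C01"], cohorts["C02"]
        assert t1.related_pairs == t2.related_pairs
        assert e1.gene_ids == e2.gene_ids
        assert not np.allclose(e1.values.to_numpy(), e2.values.to_numpy())


class TestCancerSpecificPlanting:
    def test_disjoint_blocks_across_cancers(self):
        from lncm6a.simulate import specific_lncrna_ids

        cfg = SimulationConfig(
            n_samples=60, n_cancers=2, n_lncrnas=40, n_mrnas=40, n_mirnas=5,
            n_specific_lncrnas=3, seed=6,
        )
        cohorts = simulate_multi_cancer(cfg)
        (_, _, t1), (_, _, t2) = cohorts["C01"], cohorts["C02"]
        spec1 = set(specific_lncrna_ids(cfg, block=0))
        spec2 = set(specific_lncrna_ids(cfg, block=1))
        assert spec1.isdisjoint(spec2)
        assert spec1 <= t1.related_lncrnas
        assert spec2.isdisjoint(t1.related_lncrnas)
        assert spec2 <= t2.related_lncrnas

    def test_overflowing_blocks_rejected(self):
        cfg = SimulationConfig(
            n_samples=20, n_lncrnas=12, n_mrnas=40, n_mirnas=5,
            n_specific_lncrnas=10, specific_block=1, seed=6,
        )
        with pytest.raises(ValueError, match="planted"):
            simulate_cohort(cfg)
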