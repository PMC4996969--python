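"""Cohort generator: HWE genotypes, equal-effect liability model, DAS28/EULAR."""

import numpy as np
import pandas as pd
import pytest

from rxbench.cohort import (
    CohortConfig,
    GenotypeMatrix,
    assign_effects,
    eular_classify,
    generate_cohort,
    simulate_das28,
    simulate_genotypes,
    simulate_liability_outcome,
    split_cohort,
)


class TestSimulateGenotypes:
    def test_hwe_proportions_at_half(self):
        cfg = CohortConfig(n_subjects=10000, n_snps=5, maf_range=(0.5, 0.5), seed=1)
        g = simulate_genotypes(cfg)
        for j in range(g.n_snps):
            counts = np.bincount(g.dosages[:, j].astype(int), minlength=3) / 10000
            se = 3 * np.sqrt(0.25 * 0.75 / 10000)
            assert abs(counts[0] - 0.25) < se
            assert abs(counts[1] - 0.50) < 3 * np.sqrt(0.5 * 0.5 / 10000)
            assert abs(counts[2] - 0.25) < se

    def test_allele_frequency_recovery(self):
        cfg = CohortConfig(n_subjects=50000, n_snps=3, maf_range=(0.2, 0.2), seed=2)
        g = simulate_genotypes(cfg)
        se = np.sqrt(0.2 * 0.8 / (2 * 50000))
        assert np.all(np.abs(g.allele_freqs - 0.2) < 3 * se)

    def test_zero_snps_rejected(self):
        cfg = CohortConfig(n_subjects=10, n_snps=0, n_causal=0, h2_liability=0.0)
        with pytest.raises(ValueError):
            simulate_genotypes(cfg)

    def test_missingness_recorded(self):
        cfg = CohortConfig(n_subjects=500, n_snps=50, missing_rate=0.1, seed=3)
        g = simulate_genotypes(cfg)
        assert 0.05 < g.missing_fraction < 0.15

    def test_reproducible(self):
        cfg = CohortConfig(n_subjects=100, n_snps=40, seed=11)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)


class TestAssignEffects:
    def test_zero_heritability_gives_zero_effects(self):
        g = simulate_genotypes(CohortConfig(n_subjects=50, n_snps=20, seed=0))
        assert np.all(assign_effects(g, 5, 0.0) == 0)

    def test_single_locus_closed_form(self):
        # one causal SNP at p = 0.5: 2p(1-p) beta^2 = h2 -> beta = sqrt(0.18/0.5)
        dos = np.array([[0.0], [1.0], [2.0], [1.0]])
        g = GenotypeMatrix(dos, ["rs1"], np.array([0.5]))
        eff = assign_effects(g, 1, 0.18)
        assert eff[0] == pytest.approx(np.sqrt(0.18 / 0.5))

    def test_requires_causal_snps_for_positive_h2(self):
        g = simulate_genotypes(CohortConfig(n_subjects=50, n_snps=20, seed=0))
        with pytest.raises(ValueError):
            assign_effects(g, 0, 0.2)

    def test_genetic_variance_matches_target(self):
        cfg = CohortConfig(
            n_subjects=20000, n_snps=40, n_causal=20, h2_liability=0.3, seed=5
        )
        g = simulate_genotypes(cfg)
        eff = assign_effects(g, 20, 0.3, seed=5)
        score = (g.dosages - 2 * g.allele_freqs) @ eff
        assert np.var(score) == pytest.approx(0.3, abs=0.02)


class TestLiabilityOutcome:
    def test_prevalence_converges(self):
        cfg = CohortConfig(
            n_subjects=100000, n_snps=20, n_causal=10, h2_liability=0.18, seed=6
        )
        g = simulate_genotypes(cfg)
        eff = assign_effects(g, 10, 0.18, seed=6)
        labels, _ = simulate_liability_outcome(g, eff, 0.217, seed=6)
        assert labels.mean() == pytest.approx(0.217, abs=0.004)

    def test_no_heritability_means_labels_independent_of_genotype(self):
        cfg = CohortConfig(n_subjects=20000, n_snps=10, seed=7)
        g = simulate_genotypes(cfg)
        labels, _ = simulate_liability_outcome(g, np.zeros(10), 0.3, seed=7)
        score = g.dosages.sum(axis=1)
        r = np.corrcoef(score, labels.astype(float))[0, 1]
        assert abs(r) < 0.03

    def test_high_heritability_separates_deciles(self):
        cfg = CohortConfig(
            n_subjects=20000, n_snps=30, n_causal=10, h2_liability=0.9, seed=8
        )
        g = simulate_genotypes(cfg)
        eff = assign_effects(g, 10, 0.9, seed=8)
        labels, _ = simulate_liability_outcome(g, eff, 0.217, seed=8)
        score = (g.dosages - 2 * g.allele_freqs) @ eff
        q = np.quantile(score, [0.1, 0.9])
        assert labels[score >= q[1]].mean() > labels[score <= q[0]].mean()

    def test_exact_prevalence_count(self):
        cfg = CohortConfig(n_subjects=591, n_snps=10, n_causal=5, h2_liability=0.2, seed=9)
        g = simulate_genotypes(cfg)
        eff = assign_effects(g, 5, 0.2, seed=9)
        labels, _ = simulate_liability_outcome(g, eff, 0.357, seed=9, exact_prevalence=True)
        assert labels.sum() == 211  # round(0.357 * 591)

    def test_invalid_prevalence(self):
        g = simulate_genotypes(CohortConfig(n_subjects=10, n_snps=5, seed=0))
        with pytest.raises(ValueError):
            simulate_liability_outcome(g, np.zeros(5), 1.5)


class TestEular:
    @pytest.mark.parametrize(
        "baseline,followup,expected",
        [
            (6.0, 3.0, "Good"),  # improvement 3.0 > 1.2, endpoint <= 3.2
            (6.0, 6.0, "None"),  # no improvement
            (6.0, 5.2, "None"),  # improvement 0.8, endpoint > 5.1
            (6.0, 4.5, "Moderate"),  # improvement 1.5, endpoint > 3.2
            (5.0, 4.2, "Moderate"),  # improvement 0.8, endpoint <= 5.1
            (8.0, 7.5, "None"),  # improvement 0.5
        ],
    )
    def test_table(self, baseline, followup, expected):
        assert eular_classify(baseline, followup) == expected

    def test_negative_das28_rejected(self):
        with pytest.raises(ValueError):
            eular_classify(6.0, -0.1)

    def test_low_baseline_rejected(self):
        with pytest.raises(ValueError):
            eular_classify(3.0, 2.0)


class TestSimulateDas28:
    def test_roundtrip_reproduces_labels(self):
        rng = np.random.default_rng(0)
        labels = rng.random(500) < 0.217
        table = simulate_das28(labels, seed=1)
        assert np.array_equal(table["nonresponse"].to_numpy(), labels)
        assert np.array_equal(np.asarray(table["eular"]) == "None", labels)

    def test_all_nonresponders(self):
        table = simulate_das28(np.ones(50, dtype=bool), seed=2)
        assert (np.asarray(table["eular"]) == "None").all()

    def test_prevalence_preserved_exactly(self):
        labels = np.zeros(1000, dtype=bool)
        labels[:217] = True
        table = simulate_das28(labels, seed=3)
        assert table["nonresponse"].mean() == pytest.approx(0.217)

    def test_baseline_range_and_delta_identity(self):
        labels = np.random.default_rng(4).random(300) < 0.3
        table = simulate_das28(labels, seed=4)
        assert (table["das28_baseline"] > 3.2).all()
        assert (table["das28_baseline"] <= 9.4).all()
        assert (table["das28_followup"] >= 0).all()
        np.testing.assert_allclose(
            table["delta_das28"],
            table["das28_baseline"] - table["das28_followup"],
            atol=1e-10,
        )

    def test_improvement_decreases_with_liability_among_responders(self):
        rng = np.random.default_rng(5)
        liab = rng.normal(size=2000)
        labels = liab > np.quantile(liab, 0.783)
        table = simulate_das28(labels, liabilities=liab, seed=5)
        resp = ~labels
        r = np.corrcoef(liab[resp], table["delta_das28"].to_numpy()[resp])[0, 1]
        assert r < -0.1


class TestSplitAndGenerate:
    def test_split_counts(self):
        table = pd.DataFrame({"subject_id": [f"S{i}" for i in range(3297)]})
        out = split_cohort(table, sizes=(2031, 675, 591), seed=0)
        counts = out["split"].value_counts()
        assert counts["train"] == 2031
        assert counts["leaderboard"] == 675
        assert counts["test"] == 591

    def test_split_all_train(self):
        table = pd.DataFrame({"subject_id": ["a", "b", "c"]})
        out = split_cohort(table, sizes=(3, 0, 0), seed=0)
        assert (out["split"] == "train").all()

    def test_split_deterministic(self):
        table = pd.DataFrame({"subject_id": [f"S{i}" for i in range(100)]})
        a = split_cohort(table, sizes=(60, 20, 20), seed=5)
        b = split_cohort(table, sizes=(60, 20, 20), seed=5)
        assert (a["split"] == b["split"]).all()

    def test_split_oversubscribed(self):
        table = pd.DataFrame({"subject_id": ["a", "b"]})
        with pytest.raises(ValueError):
            split_cohort(table, sizes=(2, 1, 0))

    def test_generate_cohort_reproducible(self, small_cohort):
        cfg, genotypes, table, effects = small_cohort
        g2, t2, e2 = generate_cohort(cfg)
        np.testing.assert_array_equal(genotypes.dosages, g2.dosages)
        pd.testing.assert_frame_equal(table, t2)
        np.testing.assert_array_equal(effects, e2)

    def test_drug_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortConfig(drug_mix={"adalimumab": 0.5, "etanercept": 0.4})
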