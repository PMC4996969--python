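"""Bootstrap rank robustness, random-feature nulls, KS enrichment, paired tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_rel

from rxbench.robustness import (
    bootstrap_scores,
    ks_uniform_enrichment,
    p_upper_bound,
    paired_comparison_by_subset,
    paired_model_comparison,
    random_feature_null,
    robustly_better,
)
from rxbench.scoring import Submission


def _label_table(n=80, n_pos=30, seed=0):
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=bool)
    y[rng.choice(n, n_pos, replace=False)] = True
    return pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)], "nonresponse": y})


def _submission(table, noise, seed, team):
    rng = np.random.default_rng(seed)
    y = table["nonresponse"].to_numpy(float)
    scores = y + rng.normal(0, noise, len(y))
    return Submission(list(table["subject_id"]), scores, team=team)


class TestBootstrap:
    def test_identical_submissions_identical_scores(self):
        table = _label_table()
        a = _submission(table, 1.0, 1, "a")
        b = Submission(a.subject_ids, a.scores.copy(), team="b")
        boot = bootstrap_scores([a, b], table, B=50, seed=3)
        np.testing.assert_array_equal(boot.aupr[:, 0], boot.aupr[:, 1])
        np.testing.assert_array_equal(boot.auroc[:, 0], boot.auroc[:, 1])

    def test_deterministic_given_seed(self):
        table = _label_table()
        subs = [_submission(table, 0.8, s, f"t{s}") for s in range(3)]
        b1 = bootstrap_scores(subs, table, B=60, seed=9)
        b2 = bootstrap_scores(subs, table, B=60, seed=9)
        np.testing.assert_array_equal(b1.aupr, b2.aupr)
        np.testing.assert_array_equal(b1.overall_rank, b2.overall_rank)

    def test_dominated_submission_ranks_last(self):
        table = _label_table()
        y = table["nonresponse"].to_numpy(float)
        perfect = Submission(list(table["subject_id"]), y, team="perfect")
        flipped = Submission(list(table["subject_id"]), 1 - y, team="flipped")
        noise = _submission(table, 2.0, 5, "noise")
        boot = bootstrap_scores([perfect, flipped, noise], table, B=100, seed=1)
        assert (boot.overall_rank[:, 1] == 3.0).mean() >= 0.95
        assert (boot.overall_rank[:, 0] == 1.0).mean() >= 0.95

    def test_needs_two_submissions(self):
        table = _label_table()
        with pytest.raises(ValueError):
            bootstrap_scores([_submission(table, 1.0, 1, "a")], table, B=10)


class TestRobustlyBetter:
    def test_self_comparison_rejected(self):
        table = _label_table()
        subs = [_submission(table, 0.8, s, f"t{s}") for s in range(2)]
        boot = bootstrap_scores(subs, table, B=30, seed=2)
        with pytest.raises(ValueError):
            robustly_better(boot, 0, 0)

    def test_identical_submissions_not_robustly_better(self):
        table = _label_table()
        a = _submission(table, 1.0, 1, "a")
        b = Submission(a.subject_ids, a.scores.copy(), team="b")
        boot = bootstrap_scores([a, b], table, B=40, seed=3)
        decision, p = robustly_better(boot, "a", "b")
        assert not decision
        assert p == 1.0

    def test_dominant_submission_extreme_p(self):
        table = _label_table(n=120, n_pos=45)
        y = table["nonresponse"].to_numpy(float)
        perfect = Submission(list(table["subject_id"]), y, team="a")
        weak = _submission(table, 3.0, 4, "b")
        boot = bootstrap_scores([perfect, weak], table, B=1000, seed=5)
        decision, p = robustly_better(boot, "a", "b")
        assert decision
        assert p < 1e-6

    def test_agrees_with_reference_signed_rank(self):
        """Normal-approximation Wilcoxon recomputed from first principles."""
        table = _label_table(n=100, n_pos=40, seed=6)
        subs = [_submission(table, 1.2, s, f"t{s}") for s in (21, 22)]
        boot = bootstrap_scores(subs, table, B=200, seed=7)
        _, p = robustly_better(boot, 0, 1, metric="auroc")
        d = boot.auroc[:, 0] - boot.auroc[:, 1]
        d = d[d != 0]
        from scipy.stats import norm, rankdata

        r = rankdata(np.abs(d))
        w = r[d > 0].sum()
        n = len(d)
        mu = n * (n + 1) / 4
        ties = np.unique(r, return_counts=True)[1]
        sigma2 = n * (n + 1) * (2 * n + 1) / 24 - (ties**3 - ties).sum() / 48
        z = (w - mu) / np.sqrt(sigma2)
        p_ref = 2 * norm.sf(abs(z))
        assert p == pytest.approx(p_ref, rel=1e-6)


class TestRandomFeatureNull:
    def test_observed_beats_all_nulls(self):
        exp = random_feature_null(
            lambda feats: 0.0, np.arange(50), k=5, observed_score=1.0, n_draws=100, seed=0
        )
        assert exp.empirical_p == pytest.approx(1 / 101)

    def test_constant_callback(self):
        exp = random_feature_null(
            lambda feats: 0.7, np.arange(50), k=5, observed_score=0.7, n_draws=50, seed=1
        )
        assert exp.empirical_p == 1.0
        assert np.all(exp.null_scores == 0.7)

    def test_observed_below_null_median(self):
        rng = np.random.default_rng(2)
        exp = random_feature_null(
            lambda feats: float(rng.normal()),
            np.arange(50),
            k=5,
            observed_score=-2.0,
            n_draws=100,
            seed=2,
        )
        assert exp.empirical_p > 0.5

    def test_k_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            random_feature_null(lambda f: 0.0, np.arange(5), k=6, observed_score=0.0)


class TestKsEnrichment:
    def test_all_ones_anti_enriched(self):
        assert ks_uniform_enrichment(np.ones(6)) > 0.99

    def test_seven_tiny_pvalues(self):
        # D+ = 1 - 1/101; exact one-sided KS for n = 7 is far below 1e-4
        assert ks_uniform_enrichment(np.full(7, 1 / 101)) < 1e-4

    def test_uniform_calibration(self):
        rng = np.random.default_rng(3)
        ps = [ks_uniform_enrichment(rng.random(20)) for _ in range(200)]
        ps = np.array(ps)
        assert 0.4 < ps.mean() < 0.6
        assert (ps < 0.05).mean() < 0.12

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ks_uniform_enrichment([0.1, 0.2])
        with pytest.raises(ValueError):
            ks_uniform_enrichment([0.0, 0.5, 0.7])


class TestPUpperBound:
    def test_all_hits(self):
        assert p_upper_bound(100, 100) == 1.0

    def test_zero_hits_closed_form(self):
        # 1 - (1 - 0.9987)^(1/100)
        expected = 1 - 0.0013 ** (1 / 100)
        assert p_upper_bound(0, 100, 0.9987) == pytest.approx(expected, rel=1e-6)

    def test_bound_exceeds_empirical(self):
        for hits in (0, 3, 20, 77):
            emp = (1 + hits) / 101
            assert p_upper_bound(hits, 100) >= emp - 0.01

    def test_monotone_in_confidence(self):
        assert p_upper_bound(5, 100, 0.99) < p_upper_bound(5, 100, 0.9987)


class TestPairedComparison:
    def test_identical_models_give_p_one(self):
        vals = {f"t{i}": 0.6 + 0.01 * i for i in range(5)}
        assert paired_model_comparison(vals, dict(vals)) == 1.0

    def test_uniform_improvement_detected(self):
        clin = {f"t{i}": 0.55 + 0.01 * i for i in range(6)}
        full = {t: v + 0.1 for t, v in clin.items()}
        assert paired_model_comparison(full, clin) < 0.01

    def test_matches_reference_t(self):
        rng = np.random.default_rng(4)
        full = rng.normal(0.6, 0.05, 7)
        clin = full - rng.normal(0.01, 0.02, 7)
        assert paired_model_comparison(full, clin) == pytest.approx(
            float(ttest_rel(full, clin).pvalue)
        )

    def test_unpaired_teams_rejected(self):
        with pytest.raises(ValueError):
            paired_model_comparison({"a": 0.5, "b": 0.6, "c": 0.7}, {"a": 0.5, "d": 0.6, "e": 0.7})

    def test_per_subset_bonferroni(self):
        table = _label_table(n=120, n_pos=48, seed=8)
        full = {f"t{i}": _submission(table, 1.0, 10 + i, f"t{i}") for i in range(4)}
        clin = {f"t{i}": _submission(table, 1.0, 20 + i, f"t{i}") for i in range(4)}
        rng = np.random.default_rng(9)
        groups = rng.choice(["d1", "d2"], 120)
        subsets = {d: groups == d for d in ("d1", "d2")}
        out = paired_comparison_by_subset(full, clin, table, subsets, metric="auroc")
        for d in subsets:
            assert out[d]["p_bonferroni"] == pytest.approx(min(1.0, 2 * out[d]["p"]))
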