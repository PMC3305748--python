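import numpy as np
import pytest
from scipy import stats

from eqcm import (
    ClinicalTable,
    ModuleSpec,
    SubNetwork,
    SyntheticConfig,
    generate,
    genes_survival_test,
    km_curve,
    kmeans_bipartition,
    logrank_test,
    subnetwork_survival_test,
)

from oracles import kaplan_meier_at, logrank_oe_v


class TestKmCurve:
    def test_no_censoring_is_empirical_survival(self):
        times, surv = km_curve([1.0, 2.0, 3.0], [True, True, True])
        assert times[0] == 0.0 and surv[0] == 1.0
        np.testing.assert_allclose(surv[1:], [2 / 3, 1 / 3, 0.0])

    def test_all_censored_stays_at_one(self):
        _, surv = km_curve([5.0, 8.0, 2.0], [False, False, False])
        np.testing.assert_allclose(surv, 1.0)

    def test_censored_risk_set_hand_value(self):
        # n=4: censor at t=1, death at t=2 -> risk set of 3 -> S(2) = 2/3
        times, surv = km_curve([1.0, 2.0, 5.0, 6.0], [False, True, False, False])
        s_at_2 = surv[np.searchsorted(times, 2.0)]
        assert s_at_2 == pytest.approx(2 / 3)

    def test_matches_product_limit_oracle_with_mixed_censoring(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, size=30).round(1)
        e = rng.random(30) < 0.6
        times, surv = km_curve(t, e)
        for q in (1.0, 5.0, 15.0):
            idx = np.searchsorted(times, q, side="right") - 1
            assert surv[idx] == pytest.approx(kaplan_meier_at(t, e, q))

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1.0, 2.0], [True, True])

    def test_survival_non_increasing(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(5, 50)
        e = rng.random(50) < 0.7
        _, surv = km_curve(t, e)
        assert np.all(np.diff(surv) <= 1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        chi, p = logrank_test(t, e, t, e)
        assert chi == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_oe_v_oracle_four_patients(self):
        # group A deaths {1,2}, group B deaths {3,4}, no censoring
        chi, p = logrank_test([1, 2], [True, True], [3, 4], [True, True])
        expected = logrank_oe_v([1, 2], [True, True], [3, 4], [True, True])
        assert expected == pytest.approx(49 / 17)  # O=2, E=5/6, V=17/36
        assert chi == pytest.approx(expected, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-10)

    def test_matches_oracle_with_ties_and_censoring(self):
        t1, e1 = [2, 2, 5, 7, 9], [True, True, False, True, False]
        t2, e2 = [2, 4, 4, 8, 9], [True, True, False, True, True]
        chi, _ = logrank_test(t1, e1, t2, e2)
        assert chi == pytest.approx(logrank_oe_v(t1, e1, t2, e2), rel=1e-10)

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(2)
        t1, t2 = rng.exponential(5, 20), rng.exponential(8, 25)
        e1, e2 = rng.random(20) < 0.7, rng.random(25) < 0.7
        assert logrank_test(t1, e1, t2, e2)[0] == pytest.approx(
            logrank_test(t2, e2, t1, e1)[0]
        )

    def test_invariant_under_monotone_time_transform(self):
        rng = np.random.default_rng(3)
        t1, t2 = rng.exponential(5, 20), rng.exponential(8, 20)
        e1 = e2 = np.ones(20, bool)
        chi_raw, _ = logrank_test(t1, e1, t2, e2)
        chi_log, _ = logrank_test(np.log1p(t1), e1, np.log1p(t2), e2)
        assert chi_raw == pytest.approx(chi_log, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [True])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1.0], [False], [2.0], [False])

    def test_permutation_null_pvalues_uniform(self):
        rng = np.random.default_rng(0)
        n = 60
        t = rng.exponential(300, n)
        e = rng.random(n) < 0.7
        ps = []
        for _ in range(1000):
            lab = rng.permutation(n) < n // 2
            ps.append(logrank_test(t[lab], e[lab], t[~lab], e[~lab])[1])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestKmeansBipartition:
    def _two_prototype_data(self, rng, n_per=30, p=20, noise=0.3):
        proto = rng.standard_normal(p)
        X = np.vstack(
            [
                proto + noise * rng.standard_normal((n_per, p)),
                -proto + noise * rng.standard_normal((n_per, p)),
            ]
        )
        labels = np.repeat([0, 1], n_per)
        return X, labels

    def test_recovers_anticorrelated_prototypes(self):
        rng = np.random.default_rng(1)
        X, truth = self._two_prototype_data(rng)
        got = kmeans_bipartition(X, replicates=20, rng_seed=0)
        agree = max((got == truth).mean(), (got != truth).mean())
        assert agree == 1.0

    def test_scaled_copy_coclusters(self):
        rng = np.random.default_rng(5)
        X, _ = self._two_prototype_data(rng, n_per=10)
        X = np.vstack([X, 2.0 * X[0]])  # scale-invariant distance
        got = kmeans_bipartition(X, replicates=20, rng_seed=0)
        assert got[-1] == got[0]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 10))
        a = kmeans_bipartition(X, replicates=100, rng_seed=42)
        b = kmeans_bipartition(X, replicates=100, rng_seed=42)
        np.testing.assert_array_equal(a, b)

    def test_both_clusters_non_empty(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((25, 5))
        got = kmeans_bipartition(X, replicates=30, rng_seed=1)
        assert 0 < got.sum() < len(got)

    def test_degenerate_matrix_rejected(self):
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        with pytest.raises(ValueError, match="degenerate|identical"):
            kmeans_bipartition(X, replicates=5, rng_seed=0)

    def test_zero_variance_sample_rejected(self):
        X = np.random.default_rng(0).standard_normal((5, 4))
        X[2] = 7.0
        with pytest.raises(ValueError, match="zero-variance"):
            kmeans_bipartition(X, replicates=5, rng_seed=0)


class TestSubnetworkSurvivalTest:
    def test_planted_prognostic_module_is_detected(self):
        cfg = SyntheticConfig(
            n_genes=100,
            n_samples=200,
            modules=(ModuleSpec(15, 0.85, 3.0),),
            rng_seed=1,
        )
        expr, clin, truth = generate(cfg)
        sub = SubNetwork(frozenset(truth["modules"]["module1"]), 0.85, id="M1")
        res = subnetwork_survival_test(sub, expr, clin, rng_seed=0)
        assert res.pvalue < 0.01

    def test_group_label_polarity_does_not_change_p(self, small_dataset):
        expr, clin, truth = small_dataset
        sub = SubNetwork(frozenset(truth["modules"]["module1"]), 0.85, id="M1")
        res = subnetwork_survival_test(sub, expr, clin, rng_seed=3)
        t, e = clin.subset(res.sample_ids)
        g = res.group_labels.astype(bool)
        chi_sw, p_sw = logrank_test(t[~g], e[~g], t[g], e[g])
        assert p_sw == pytest.approx(res.pvalue, rel=1e-10)

    def test_missing_clinical_samples_dropped_with_warning(self, small_dataset):
        expr, clin, truth = small_dataset
        short = ClinicalTable(clin.sample_ids[:-5], clin.time[:-5], clin.event[:-5])
        sub = SubNetwork(frozenset(truth["modules"]["module1"]), 0.85, id="M1")
        with pytest.warns(UserWarning, match="missing from clinical"):
            res = subnetwork_survival_test(sub, expr, short, rng_seed=0)
        assert len(res.sample_ids) == expr.n_samples - 5

    def test_no_shared_samples_rejected(self, small_dataset):
        expr, clin, truth = small_dataset
        alien = ClinicalTable(["zz1", "zz2"], [1.0, 2.0], [True, True])
        sub = SubNetwork(frozenset(truth["modules"]["module1"]), 0.85, id="M1")
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="shared"):
                subnetwork_survival_test(sub, expr, alien, rng_seed=0)

    def test_unknown_gene_rejected(self, small_dataset):
        expr, clin, _ = small_dataset
        sub = SubNetwork(frozenset({"nope1", "nope2"}), 0.0, id="X")
        with pytest.raises(KeyError):
            subnetwork_survival_test(sub, expr, clin, rng_seed=0)

    def test_null_type_one_error_near_nominal(self, null_dataset):
        # survival independent of expression: fraction of p<0.05 ~ 5%
        expr, clin, _ = null_dataset
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            genes = list(rng.choice(expr.gene_ids, size=12, replace=False))
            res = genes_survival_test(
                genes, expr, clin, rng_seed=i, replicates=20, test_id=f"r{i}"
            )
            hits += res.pvalue < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.035)
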