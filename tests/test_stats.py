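"""Rank tests, EMD clustering and ΔNSR regression."""

import numpy as np
import pytest
from scipy import stats as sps

from mmskit import (
    cluster_tree,
    delta_linear_fit,
    emd_matrix,
    friedman_test,
    kruskal_multcompare,
    ranksum_matrix,
)


class TestRanksumMatrix:
    def test_identical_groups_near_one(self, rng):
        x = rng.normal(size=30)
        m = ranksum_matrix({"a": x, "b": x.copy()})
        assert m.p_values[0, 1] > 0.99
        assert np.all(np.diag(m.p_values) == 1.0)

    def test_large_shift_detected(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        m = ranksum_matrix({"a": a, "b": b})
        assert m.p_values[0, 1] < 1e-6

    def test_matrix_is_symmetric(self, rng):
        groups = {k: rng.normal(size=20) for k in "abcd"}
        m = ranksum_matrix(groups)
        np.testing.assert_array_equal(m.p_values, m.p_values.T)

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.gamma(2, 1, 25), rng.gamma(3, 1, 25)
        p1 = ranksum_matrix({"a": a, "b": b}).p_values[0, 1]
        p2 = ranksum_matrix({"a": np.log(a), "b": np.log(b)}).p_values[0, 1]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_small_group_excluded_with_warning(self, rng):
        with pytest.warns(UserWarning, match="below size floor"):
            m = ranksum_matrix({"a": rng.normal(size=10), "b": np.array([1.0, 2.0])})
        assert m.labels == ("a",)


class TestKruskal:
    def test_identical_groups_null(self):
        g = {k: np.full(5, 2.0) for k in "abc"}
        res = kruskal_multcompare(g)
        assert res.chi2 == 0.0 and res.p_value == 1.0
        assert not res.significant.any()

    def test_matches_hand_ranked_statistic(self):
        # 3 groups x 4 values, no ties: chi2 = 12/(N(N+1)) sum n_i Rbar_i^2 - 3(N+1)
        groups = {
            "a": np.array([1.0, 3.0, 5.0, 7.0]),
            "b": np.array([2.0, 4.0, 6.0, 8.0]),
            "c": np.array([9.0, 10.0, 11.0, 12.0]),
        }
        ranks = {"a": [1, 3, 5, 7], "b": [2, 4, 6, 8], "c": [9, 10, 11, 12]}
        n_tot = 12
        expected = 12.0 / (n_tot * (n_tot + 1)) * sum(
            4 * np.mean(r) ** 2 for r in ranks.values()
        ) - 3 * (n_tot + 1)
        res = kruskal_multcompare(groups)
        assert res.chi2 == pytest.approx(expected, rel=1e-12)

    def test_only_shifted_group_flagged(self, rng):
        g = {
            "a": rng.normal(0, 1, 20),
            "b": rng.normal(0, 1, 20),
            "c": rng.normal(8, 1, 20),
        }
        res = kruskal_multcompare(g)
        i = res.labels.index("c")
        for j, lab in enumerate(res.labels):
            if lab != "c":
                assert res.significant[i, j]
        ia, ib = res.labels.index("a"), res.labels.index("b")
        assert not res.significant[ia, ib]

    def test_two_groups_redirected(self, rng):
        with pytest.raises(ValueError, match="ranksum"):
            kruskal_multcompare({"a": rng.normal(size=5), "b": rng.normal(size=5)})


class TestFriedman:
    def test_identical_columns_null(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 3))
        chi2, p = friedman_test(x)
        assert chi2 == 0.0 and p == 1.0

    def test_matches_scipy_for_three_conditions(self, rng):
        x = rng.normal(size=(12, 3))
        chi2, p = friedman_test(x)
        ref = sps.friedmanchisquare(x[:, 0], x[:, 1], x[:, 2])
        assert chi2 == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_row_permutation_invariance(self, rng):
        x = rng.normal(size=(10, 4))
        chi2_a, _ = friedman_test(x)
        chi2_b, _ = friedman_test(x[rng.permutation(10)])
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)

    def test_two_condition_shift_agrees_with_sign_test(self, rng):
        # consistent one-sided shift: Friedman significant like a sign test
        a = rng.normal(0, 1, 15)
        x = np.column_stack([a, a + 2.0])
        chi2, p = friedman_test(x)
        assert p < 0.001

    def test_incomplete_block_rejected(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError, match="incomplete"):
            friedman_test(x)


class TestEMD:
    def test_identical_samples_zero(self, rng):
        x = rng.gamma(2, 0.1, 100)
        m = emd_matrix({"a": x, "b": x.copy()})
        assert m.distances[0, 1] == 0.0

    def test_translation_exactness(self):
        x = np.full(50, 0.3)
        m = emd_matrix({"a": x, "b": x + 0.2})
        assert m.distances[0, 1] == pytest.approx(0.2, abs=1e-12)

    def test_matches_quantile_integral_oracle(self, rng):
        # equal-size samples: W1 = mean |sorted difference|
        for _ in range(10):
            a, b = rng.gamma(2, 0.1, 80), rng.gamma(3, 0.08, 80)
            m = emd_matrix({"a": a, "b": b})
            oracle = np.mean(np.abs(np.sort(a) - np.sort(b)))
            assert m.distances[0, 1] == pytest.approx(oracle, abs=1e-9)

    def test_metric_axioms_on_random_triples(self, rng):
        samples = {i: rng.gamma(rng.uniform(1, 4), rng.uniform(0.05, 0.3), 60)
                   for i in range(10)}
        m = emd_matrix(samples)
        d = m.distances
        assert np.all(np.diag(d) == 0)
        np.testing.assert_array_equal(d, d.T)
        idx = rng.integers(0, 10, size=(100, 3))
        for i, j, k in idx:
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestClusterTree:
    def test_two_blobs_split_perfectly(self, rng):
        samples = {}
        cond = {}
        for i in range(8):
            samples[f"lo{i}"] = rng.normal(0.1, 0.01, 60)
            cond[f"lo{i}"] = "control"
            samples[f"hi{i}"] = rng.normal(0.9, 0.01, 60)
            cond[f"hi{i}"] = "pain"
        emd = emd_matrix(samples)
        cl = cluster_tree(emd, k=2, conditions=cond)
        lo_ids = {cl.labels[i] for i, lab in enumerate(emd.labels) if lab.startswith("lo")}
        hi_ids = {cl.labels[i] for i, lab in enumerate(emd.labels) if lab.startswith("hi")}
        assert len(lo_ids) == 1 and len(hi_ids) == 1 and lo_ids != hi_ids
        for comp in cl.composition.values():
            assert sum(comp.values()) == pytest.approx(100.0)
            assert set(comp) in ({"control"}, {"pain"})

    def test_k_equals_n_gives_singletons(self, rng):
        samples = {i: rng.normal(i, 0.1, 50) for i in range(5)}
        emd = emd_matrix(samples)
        cl = cluster_tree(emd, k=5)
        assert sorted(cl.labels) == [1, 2, 3, 4, 5]
        assert all(list(c.values()) == [100.0] for c in cl.composition.values())

    def test_partition_invariant_to_input_order(self, rng):
        vals = {i: rng.normal(rng.uniform(0, 1), 0.05, 50) for i in range(9)}
        m1 = emd_matrix(dict(sorted(vals.items())))
        m2 = emd_matrix(dict(sorted(vals.items(), reverse=True)))
        c1, c2 = cluster_tree(m1, k=3), cluster_tree(m2, k=3)

        def partition(m, c):
            groups = {}
            for lab, cid in zip(m.labels, c.labels):
                groups.setdefault(cid, set()).add(lab)
            return sorted(map(frozenset, groups.values()), key=sorted)

        assert partition(m1, c1) == partition(m2, c2)

    def test_k_larger_than_n_rejected(self, rng):
        emd = emd_matrix({i: rng.normal(size=40) for i in range(3)})
        with pytest.raises(ValueError, match="outside"):
            cluster_tree(emd, k=5)


class TestDeltaLinearFit:
    def test_collinear_pairs_perfect_fit(self):
        x = np.linspace(-1, 1, 10)
        res = delta_linear_fit(2.0 * x + 0.5, x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.5)
        assert res.r_squared == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)

    def test_calibrated_cohort_hits_target_r2(self, rng):
        # the synthetic calibration: noise sd chosen so E[R^2] ~ target
        target, ratio, n = 0.84, 0.6, 21
        r2s = []
        for _ in range(100):
            dh = rng.uniform(0.02, 0.06, n)
            signal = ratio * dh
            noise_sd = np.std(signal) * np.sqrt(1 / target - 1)
            df = signal + rng.normal(0, noise_sd, n)
            r2s.append(delta_linear_fit(df, dh).r_squared)
        assert np.mean(r2s) == pytest.approx(target, abs=0.08)

    def test_null_r2_follows_beta_distribution(self, rng):
        # independent pairs: R^2 ~ Beta(1/2, (n-2)/2)
        n = 21
        r2s = [
            delta_linear_fit(rng.normal(size=n), rng.normal(size=n)).r_squared
            for _ in range(500)
        ]
        _, p = sps.kstest(r2s, sps.beta(0.5, (n - 2) / 2).cdf)
        assert p > 0.01

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            delta_linear_fit(np.ones(2), np.ones(2))
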