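"""Hierarchical statistics: aggregation, ANOVA, Newman-Keuls, t test,
effect sizes.  The ANOVA/t oracles are hand-expanded closed forms computed
inside the tests; the Newman-Keuls oracle is an independent brute-force
implementation of the stepwise rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from endoquant import stats


# --------------------------------------------------------------------------
# independent brute-force Newman-Keuls oracle


def nk_bruteforce(groups, alpha):
    """Enumerate every ordered stretch, largest first; a pair is significant
    iff its own studentized-range test rejects AND every stretch containing
    it rejected too."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    means = np.array([g.mean() for g in groups])
    ns = np.array([g.size for g in groups])
    df = sum(g.size for g in groups) - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    order = np.argsort(means, kind="stable")

    def rejects(i, j):  # ordered positions i < j
        a, b = order[i], order[j]
        r = j - i + 1
        if mse == 0:
            return means[b] != means[a]
        n_h = 2.0 / (1.0 / ns[a] + 1.0 / ns[b])
        q = (means[b] - means[a]) / np.sqrt(mse / n_h)
        return q > sps.studentized_range.ppf(1 - alpha, r, df)

    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            # all containing stretches (ii <= i, jj >= j) must reject
            ok = all(
                rejects(ii, jj)
                for ii in range(0, i + 1)
                for jj in range(j, k)
                if (ii, jj) != (i, j)
            )
            sig[order[i], order[j]] = sig[order[j], order[i]] = ok and rejects(i, j)
    return sig


class TestAggregate:
    def test_condition_sem_across_experiment_means(self):
        df = pd.DataFrame({
            "condition": "c", "experiment_id": ["e1"] * 2 + ["e2"] * 2 + ["e3"] * 2,
            "net_mean": [10, 10, 20, 20, 30, 30],
        })
        _, cond = stats.aggregate(df)
        assert cond.loc[0, "mean"] == 20.0
        assert cond.loc[0, "sem"] == pytest.approx(10.0 / np.sqrt(3))
        assert cond.loc[0, "n_experiments"] == 3

    def test_single_experiment_summary_but_tests_refused(self):
        df = pd.DataFrame({"condition": "c", "experiment_id": "e1",
                           "net_mean": [1.0, 2.0]})
        exp, cond = stats.aggregate(df)
        assert len(cond) == 1 and cond.loc[0, "n_experiments"] == 1
        assert np.isnan(cond.loc[0, "sem"])
        with pytest.raises(ValueError, match=">= 2"):
            stats.students_t([1.5], [2.5])

    def test_hierarchical_path_differs_from_pooled_cells(self):
        """Unequal cells per experiment: the experiment-level SEM is not the
        pooled-cell SEM — the aggregation order is load-bearing."""
        df = pd.DataFrame({
            "condition": "c",
            "experiment_id": ["e1"] * 8 + ["e2"] * 2,
            "net_mean": list(np.linspace(0, 7, 8)) + [100.0, 102.0],
        })
        _, cond = stats.aggregate(df)
        pooled_sem = df["net_mean"].std(ddof=1) / np.sqrt(len(df))
        assert cond.loc[0, "sem"] != pytest.approx(pooled_sem, rel=0.2)
        exp_means = df.groupby("experiment_id")["net_mean"].mean()
        assert cond.loc[0, "mean"] == pytest.approx(exp_means.mean())

    def test_missing_labels_rejected(self):
        df = pd.DataFrame({"condition": ["c", None], "experiment_id": "e",
                           "net_mean": [1.0, 2.0]})
        with pytest.raises(ValueError):
            stats.aggregate(df)


class TestAnova:
    def test_worked_dataset_against_hand_expanded_sums(self):
        groups = [[1, 2, 3], [2, 3, 4], [6, 7, 8]]
        # hand-expanded closed form, written out independently of the
        # implementation: grand mean 4; SSB = 3[(2-4)^2+(3-4)^2+(7-4)^2]=42;
        # SSW = 3 groups x 2 each = 6; F = (42/2)/(6/6) = 21
        f, p = stats.one_way_anova(groups)
        assert f == pytest.approx(21.0, abs=1e-10)
        assert p == pytest.approx(float(sps.f.sf(21.0, 2, 6)), abs=1e-12)
        # cross-check the full statistic against an independent library route
        f2, p2 = sps.f_oneway(*groups)
        assert f == pytest.approx(float(f2), abs=1e-10)
        assert p == pytest.approx(float(p2), abs=1e-12)

    def test_invariance_to_shift_and_scale(self, rng):
        groups = [rng.normal(0, 1, 5) for _ in range(3)]
        f0, _ = stats.one_way_anova(groups)
        f1, _ = stats.one_way_anova([7.0 + g for g in groups])
        f2, _ = stats.one_way_anova([3.5 * g for g in groups])
        assert f1 == pytest.approx(f0, rel=1e-12)
        assert f2 == pytest.approx(f0, rel=1e-12)

    def test_degenerate_all_equal_is_undefined(self):
        f, p = stats.one_way_anova([[1.0, 1.0], [1.0, 1.0]])
        assert np.isnan(f) and np.isnan(p)

    def test_near_identical_groups_not_significant(self):
        f, p = stats.one_way_anova([[1.0, 1.001], [1.0005, 1.0], [0.999, 1.0]])
        assert p > 0.05

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        n = 2000
        for _ in range(n):
            _, p = stats.one_way_anova([rng.normal(0, 1, 3) for _ in range(3)])
            hits += p < 0.05
        assert hits / n == pytest.approx(0.05, abs=0.015)


class TestNewmanKeuls:
    def test_two_groups_reduce_to_studentized_range_test(self, rng):
        for _ in range(20):
            g1, g2 = rng.normal(0, 1, 4), rng.normal(0.8, 1, 4)
            out = stats.newman_keuls([g1, g2], alpha=0.05)
            df = 6
            mse = (((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()) / df
            q = abs(g1.mean() - g2.mean()) / np.sqrt(mse / 4)
            expected = q > sps.studentized_range.ppf(0.95, 2, df)
            assert bool(out.iloc[0, 1]) == bool(expected)

    def test_separated_pair_significant_tied_pair_not(self, rng):
        g = [rng.normal(0, 0.05, 4), rng.normal(0, 0.05, 4), rng.normal(10, 0.05, 4)]
        out = stats.newman_keuls(g, alpha=0.05, labels=["a", "b", "c"])
        assert out.loc["a", "c"] and out.loc["b", "c"]
        assert not out.loc["a", "b"]

    def test_matches_bruteforce_on_random_instances(self, rng):
        """Stepwise decisions identical to direct enumeration over all
        stretches on random 4-group instances (mixed null/shifted means,
        unequal n)."""
        for trial in range(60):
            k = 4
            shifts = rng.choice([0.0, 0.0, 1.5, 3.0], size=k, replace=True)
            groups = [rng.normal(shifts[i], 1.0, rng.integers(3, 6)) for i in range(k)]
            mine = stats.newman_keuls(groups, alpha=0.05).to_numpy()
            oracle = nk_bruteforce(groups, alpha=0.05)
            np.testing.assert_array_equal(mine, oracle)

    def test_blocking_coherence(self, rng):
        """If the stretch spanning a pair is non-significant, no pair inside
        it is reported significant."""
        for trial in range(30):
            groups = [rng.normal(rng.uniform(0, 2), 1.0, 4) for _ in range(5)]
            out = stats.newman_keuls(groups, alpha=0.05).to_numpy()
            means = [np.mean(g) for g in groups]
            order = np.argsort(means)
            k = 5
            for i in range(k):
                for j in range(i + 1, k):
                    if not out[order[i], order[j]]:
                        for ii in range(i, j + 1):
                            for jj in range(ii + 1, j + 1):
                                assert not out[order[ii], order[jj]]

    def test_family_error_under_complete_null(self, rng):
        hits = 0
        n = 2000
        for _ in range(n):
            groups = [rng.normal(0, 1, 3) for _ in range(4)]
            hits += stats.newman_keuls(groups, alpha=0.05).to_numpy().any()
        assert hits / n == pytest.approx(0.05, abs=0.015)


class TestStudentsT:
    def test_identical_groups_t_zero_p_one(self):
        t, p = stats.students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_worked_pair_closed_form(self):
        """{1,2,3} vs {4,5,6}: pooled sd 1, SE = sqrt(2/3), so
        t = -3 / sqrt(2/3) = -3*sqrt(3/2)."""
        t, p = stats.students_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.0 * np.sqrt(1.5), abs=1e-10)
        assert p == pytest.approx(2 * sps.t.sf(3 * np.sqrt(1.5), 4), abs=1e-12)

    def test_welch_flag(self):
        g1, g2 = [1.0, 2.0, 3.0], [4.0, 6.0, 8.0, 10.0]
        t_p, _ = stats.students_t(g1, g2)
        t_w, _ = stats.students_t(g1, g2, welch=True)
        assert t_p != t_w

    def test_zero_variance_equal_means_undefined(self):
        t, p = stats.students_t([2.0, 2.0], [2.0, 2.0])
        assert np.isnan(t) and np.isnan(p)

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        n = 2000
        for _ in range(n):
            _, p = stats.students_t(rng.normal(0, 1, 3), rng.normal(0, 1, 3))
            hits += p < 0.05
        assert hits / n == pytest.approx(0.05, abs=0.015)


class TestEffectSize:
    def test_reduction_matches_reporting_convention(self):
        es = stats.effect_size(100.0, 64.7)
        assert es["percent_change"] == pytest.approx(-35.3)
        assert es["fold_change"] == pytest.approx(0.647)

    def test_fold_increase(self):
        es = stats.effect_size(1.0, 1.53)
        assert es["percent_change"] == pytest.approx(53.0)
        assert es["fold_change"] == pytest.approx(1.53)

    def test_no_change(self):
        es = stats.effect_size(3.7, 3.7)
        assert es["percent_change"] == 0.0 and es["fold_change"] == 1.0

    def test_delta_method_se(self):
        es = stats.effect_size(100.0, 150.0, control_sem=5.0, treated_sem=6.0)
        expected = 1.5 * np.sqrt((6.0 / 150.0) ** 2 + (5.0 / 100.0) ** 2)
        assert es["fold_change_se"] == pytest.approx(expected)
        assert es["percent_change_se"] == pytest.approx(100 * expected)

    def test_zero_control_rejected(self):
        with pytest.raises(ZeroDivisionError):
            stats.effect_size(0.0, 1.0)
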