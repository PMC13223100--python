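"""Self-implemented classical tests against published values, enumeration
oracles and the scipy/lifelines reference implementations."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from crotomr import stats_kit as sk


class TestPearsonChi2:
    @pytest.mark.parametrize("table,expected_p", [
        ([[9, 2], [13, 4], [8, 14], [3, 7]], 0.007),   # TNM stage 4x2
        ([[8, 9], [17, 17], [8, 1]], 0.084),           # differentiation 3x2
    ])
    def test_published_clinical_tables(self, table, expected_p):
        assert round(sk.pearson_chi2(table).pvalue, 3) == expected_p

    def test_identical_row_proportions(self):
        res = sk.pearson_chi2([[10, 20], [5, 10], [15, 30]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_scipy_without_correction(self, rng):
        for _ in range(10):
            t = rng.integers(1, 30, size=(3, 4))
            ours = sk.pearson_chi2(t)
            stat, p, df, _ = sps.chi2_contingency(t, correction=False)
            assert ours.statistic == pytest.approx(stat)
            assert ours.pvalue == pytest.approx(p)
            assert ours.df == df

    def test_zero_margin_raises(self):
        with pytest.raises(sk.DegenerateTableError):
            sk.pearson_chi2([[0, 0], [3, 4]])


class TestFisherExact:
    @pytest.mark.parametrize("table,expected_p", [
        ([[27, 13], [6, 14]], 0.012),   # lymph-node metastasis
        ([[30, 18], [3, 9]], 0.026),    # distant metastasis
        ([[20, 8], [13, 19]], 0.021),   # vital status
        ([[25, 17], [8, 10]], 0.397),   # recurrence
        ([[18, 15], [15, 12]], 1.000),  # sex
    ])
    def test_published_clinical_tables(self, table, expected_p):
        assert round(sk.fisher_exact_2x2(table).pvalue, 3) == expected_p

    def test_modal_table_gives_p_one(self):
        # observed cell at the hypergeometric mode: every table is as or less likely
        r1, r2, c1 = 10, 10, 10
        support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
        pmf = sps.hypergeom.pmf(support, r1 + r2, r1, c1)
        a = int(support[np.argmax(pmf)])
        res = sk.fisher_exact_2x2([[a, r1 - a], [c1 - a, r2 - (c1 - a)]])
        assert res.pvalue == pytest.approx(1.0)

    def test_zero_margin_degenerate(self):
        assert sk.fisher_exact_2x2([[0, 0], [3, 4]]).pvalue == 1.0

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0:
                continue
            ours = sk.fisher_exact_2x2(t).pvalue
            _, ref = sps.fisher_exact(t)
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_policy_dispatch(self):
        assert sk.contingency_test([[5, 2], [1, 7]]).test == "fisher_exact"
        assert sk.contingency_test([[5, 2], [1, 7], [3, 3]]).test == "pearson_chi2"


def _exact_mwu_p(x, y):
    """Exhaustive permutation enumeration of the two-sided MWU p-value."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = sk.mann_whitney_u(x, x)
        assert p >= 0.99

    def test_matches_enumeration_oracle_small_n(self, rng):
        # the tie-corrected normal approximation tracks the exact permutation
        # null to ~0.01 on average at these sizes (individual draws ~0.02)
        errs = []
        for _ in range(10):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.5, 1, 5)
            _, p = sk.mann_whitney_u(x, y)
            errs.append(abs(p - _exact_mwu_p(x, y)))
        assert max(errs) < 0.02
        assert np.mean(errs) < 0.01

    def test_separated_samples(self):
        x = np.arange(20, dtype=float)
        y = x + 100
        u, p = sk.mann_whitney_u(x, y)
        assert u == 0.0 and p < 1e-6

    def test_rank_sum_alias_identity(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0.3, 1, 15)
            assert sk.wilcoxon_rank_sum(x, y) == sk.mann_whitney_u(x, y)[1]

    def test_symmetric_in_sample_swap(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.3, 1, 13)
        assert sk.wilcoxon_rank_sum(x, y) == pytest.approx(sk.wilcoxon_rank_sum(y, x))

    def test_matches_scipy(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.4, 1, 30)
        _, p = sk.mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-6)


def _exact_signed_rank_p(diffs):
    """2^n enumeration over sign assignments (no zeros)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / 2**n


class TestSignedRank:
    def test_symmetric_differences_null(self):
        assert sk.wilcoxon_signed_rank([-1, 1, -2, 2]) >= 0.99

    def test_all_zero_differences(self):
        assert sk.wilcoxon_signed_rank([0.0, 0.0]) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        errs = []
        for _ in range(10):
            d = rng.normal(0.4, 1, 10)
            d = d[d != 0]
            errs.append(abs(sk.wilcoxon_signed_rank(d) - _exact_signed_rank_p(d)))
        assert max(errs) < 0.02
        assert np.mean(errs) < 0.01

    def test_consistent_shift_significant(self):
        assert sk.wilcoxon_signed_rank(np.arange(1, 21, dtype=float)) < 0.01


class TestKruskalWallis:
    def test_identical_groups(self):
        g = [1.0, 1.0, 1.0]
        h, p = sk.kruskal_wallis([g, g, g])
        assert h == 0.0 and p == 1.0

    def test_two_group_reduction_to_mwu(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0.3, 1, 25)
            _, p_kw = sk.kruskal_wallis([x, y])
            _, p_mwu = sk.mann_whitney_u(x, y, continuity=False)
            assert abs(p_kw - p_mwu) < 0.005

    def test_strong_shift(self, rng):
        groups = [rng.normal(m, 0.5, 30) for m in (0, 2, 4)]
        _, p = sk.kruskal_wallis(groups)
        assert p < 0.001

    def test_matches_scipy(self, rng):
        groups = [rng.normal(m, 1, 15) for m in (0, 0.3, 0.8, 0.1)]
        h, p = sk.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert sk.spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert sk.spearman(x, -x**3)[0] == pytest.approx(-1.0)

    def test_ties_match_rank_then_correlate_oracle(self, rng):
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float) + 0.1 * x
        rho, _ = sk.spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy(self, rng):
        x = rng.normal(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 1, 40)
        rho, p = sk.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_flagged(self):
        rho, p = sk.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho) and math.isnan(p)


class TestSurvival:
    def test_hand_product_limit(self):
        # times {1, 2+, 3}: S = 2/3 after t=1, 0 after t=3
        curve = sk.km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve.survival_at(0.5) == 1.0
        assert curve.survival_at(1.5) == pytest.approx(2 / 3)
        assert curve.survival_at(3.5) == pytest.approx(0.0)

    def test_no_events_flat_curve_and_null_logrank(self):
        curve = sk.km_curve([5.0, 6.0, 7.0], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(100.0) == 1.0
        _, p = sk.logrank([([5.0, 6.0], [0, 0]), ([7.0, 8.0], [0, 0])])
        assert p == 1.0

    def test_curve_non_increasing_from_one(self, rng):
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        if e.sum() == 0:
            e[0] = 1
        curve = sk.km_curve(t, e)
        s = np.concatenate([[1.0], curve.survival])
        assert np.all(np.diff(s) <= 1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        t1 = rng.exponential(10, 30)
        t2 = rng.exponential(5, 25)
        e1 = (rng.random(30) < 0.7).astype(int)
        e2 = (rng.random(25) < 0.7).astype(int)
        chi2, p = sk.logrank([(t1, e1), (t2, e2)])
        ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_logrank_agrees_with_permutation_reference(self, rng):
        # n = 40 cohort; chi-square(1) tail vs 2000-label-permutation reference
        t = rng.exponential(10, 40)
        e = (rng.random(40) < 0.6).astype(int)
        grp = np.concatenate([np.zeros(20, int), np.ones(20, int)])
        t[grp == 1] *= 0.6
        chi_obs, p_asym = sk.logrank([(t[grp == 0], e[grp == 0]), (t[grp == 1], e[grp == 1])])
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(40)
            g = grp[perm]
            chi, _ = sk.logrank([(t[g == 0], e[g == 0]), (t[g == 1], e[g == 1])])
            if chi >= chi_obs - 1e-12:
                count += 1
        assert abs(p_asym - count / n_perm) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sk.logrank([([], []), ([1.0], [1])])
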