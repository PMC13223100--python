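"""MR estimators, sensitivity statistics and the Model/Results facade."""

import math

import numpy as np
import pytest

from crotomr.mr import (
    InsufficientInstrumentsError,
    MRModel,
    UndefinedRatioError,
    _weighted_median_point,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    or_from_beta,
    p_from_or_ci,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from crotomr.sumstats import HarmonizedPair
from conftest import make_pairs


class TestWaldRatio:
    def test_arithmetic(self):
        pair = HarmonizedPair("rs1", 0.5, 0.01, 0.25, 0.1, "kept")
        est = wald_ratio(pair)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome(self):
        est = wald_ratio(HarmonizedPair("rs1", 0.5, 0.01, 0.0, 0.1, "kept"))
        assert est.beta == 0.0 and est.pvalue == 1.0

    def test_zero_exposure_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(HarmonizedPair("rs1", 0.0, 0.01, 0.1, 0.1, "kept"))

    def test_model_routes_single_instrument_to_wald(self):
        pair = HarmonizedPair("rs1", 0.5, 0.01, 0.25, 0.1, "kept")
        res = MRModel([pair]).fit("ivw")
        assert res.method == "wald_ratio"
        assert res.beta == pytest.approx(wald_ratio(pair).beta)

    def test_second_order_se_is_larger(self):
        pair = HarmonizedPair("rs1", 0.5, 0.05, 0.25, 0.1, "kept")
        assert wald_ratio(pair, second_order=True).se > wald_ratio(pair).se


class TestIVW:
    def test_degenerate_homogeneity(self):
        pairs = make_pairs([0.1, 0.2, 0.4], [0.03, 0.06, 0.12], [0.01, 0.01, 0.01])
        est = ivw(pairs)
        assert est.beta == pytest.approx(0.3)
        q, _, qp = cochran_q(pairs, est)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert qp == pytest.approx(1.0)

    def test_equals_weighted_regression_through_origin(self):
        # five fixed (b_X, b_Y, s_Y) triples; generic WLS oracle
        bx = np.array([0.11, 0.23, -0.17, 0.31, 0.08])
        by = np.array([0.021, 0.055, -0.049, 0.052, 0.033])
        sy = np.array([0.01, 0.02, 0.015, 0.03, 0.012])
        w = 1.0 / sy**2
        oracle = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        est = ivw(make_pairs(bx, by, sy), random_effects=False)
        assert est.beta == pytest.approx(oracle, abs=1e-10)
        assert est.se == pytest.approx(1.0 / math.sqrt(np.sum(w * bx * bx)), abs=1e-10)

    def test_fixed_effect_se_never_exceeds_random_effects_se(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 30))
            bx = rng.normal(0.2, 0.05, k)
            by = 0.1 * bx + rng.normal(0, 0.05, k)
            sy = rng.uniform(0.01, 0.05, k)
            pairs = make_pairs(bx, by, sy)
            assert ivw(pairs, random_effects=False).se <= ivw(pairs, random_effects=True).se + 1e-15

    def test_parameter_recovery(self, rng):
        # true ratio 0.2, many strong instruments, small noise
        k = 100
        bx = rng.normal(0.3, 0.05, k)
        sy = np.full(k, 0.01)
        by = 0.2 * bx + rng.normal(0, 0.01, k)
        est = ivw(make_pairs(bx, by, sy))
        fe = ivw(make_pairs(bx, by, sy), random_effects=False)
        assert abs(est.beta - 0.2) < 3 * fe.se

    def test_requires_two_pairs(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_pairs([0.1], [0.02], [0.01]))

    def test_order_invariance(self, rng):
        bx = rng.normal(0.2, 0.05, 12)
        by = 0.1 * bx + rng.normal(0, 0.02, 12)
        sy = rng.uniform(0.01, 0.03, 12)
        pairs = make_pairs(bx, by, sy)
        est1 = ivw(pairs)
        est2 = ivw(list(reversed(pairs)))
        assert est1.beta == pytest.approx(est2.beta)
        assert est1.se == pytest.approx(est2.se)


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.05 + 0.3 * bx
        est, a, a_se, a_p = egger(make_pairs(bx, by, [0.01] * 4))
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert a == pytest.approx(0.05, abs=1e-12)

    def test_zero_pleiotropy_zero_intercept(self):
        bx = np.array([0.1, 0.25, 0.4])
        by = 0.2 * bx
        _, a, _, _ = egger(make_pairs(bx, by, [0.01] * 3))
        assert a == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(5):
            k = 12
            bx = np.abs(rng.normal(0.2, 0.05, k))
            by = 0.02 + 0.15 * bx + rng.normal(0, 0.02, k)
            sy = rng.uniform(0.01, 0.04, k)
            est, a, a_se, _ = egger(make_pairs(bx, by, sy))
            fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
            assert a == pytest.approx(fit.params[0], abs=1e-10)
            assert est.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_orientation_flip_leaves_fit_unchanged(self, rng):
        bx = rng.normal(0.2, 0.05, 10)
        by = 0.02 + 0.15 * bx + rng.normal(0, 0.02, 10)
        sy = rng.uniform(0.01, 0.04, 10)
        est1 = egger(make_pairs(bx, by, sy))
        est2 = egger(make_pairs(-bx, -by, sy))
        assert est1[0].beta == pytest.approx(est2[0].beta)
        assert est1[1] == pytest.approx(est2[1])

    def test_requires_three_pairs(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_pairs([0.1, 0.2], [0.02, 0.04], [0.01, 0.01]))


class TestWeightedMedian:
    def test_middle_point_equal_weights(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([1.0, 2.0, 10.0])
        est = weighted_median(make_pairs(bx, by, [1.0] * 3), n_boot=50, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_interpolation_midpoint_two_ratios(self):
        assert _weighted_median_point(np.array([1.0, 3.0]), np.array([1.0, 1.0])) == pytest.approx(2.0)

    def test_robust_to_forty_percent_invalid_weight(self, rng):
        # 60% of weight at ratio 0.5, 40% shifted +2, small noise
        k_valid, k_invalid = 12, 8
        bx = np.full(k_valid + k_invalid, 0.3)
        by = np.concatenate([
            0.5 * bx[:k_valid] + rng.normal(0, 0.003, k_valid),
            2.5 * bx[k_valid:] + rng.normal(0, 0.003, k_invalid),
        ])
        est = weighted_median(make_pairs(bx, by, [0.01] * (k_valid + k_invalid)),
                              n_boot=50, seed=2)
        assert abs(est.beta - 0.5) < 0.1

    def test_bootstrap_se_positive(self):
        bx = np.array([0.2, 0.3, 0.25, 0.28])
        by = 0.1 * bx
        est = weighted_median(make_pairs(bx, by, [0.01] * 4), n_boot=100, seed=3)
        assert est.se > 0


class TestWeightedMode:
    def test_degenerate_mode(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 0.25 * bx
        est = weighted_mode(make_pairs(bx, by, [0.01] * 3), n_boot=30, seed=1)
        assert est.beta == pytest.approx(0.25)
        assert est.se > 0

    def test_cluster_beats_outliers(self, rng):
        ratios = np.array([0.29, 0.30, 0.31, 0.30, 0.295, 0.305, 0.3, 2.0, 2.05])
        bx = np.full(9, 0.3)
        by = ratios * bx
        pairs = make_pairs(bx, by, [0.01] * 9)
        from crotomr.mr import _mode_bandwidth, _ratio_arrays
        theta, _ = _ratio_arrays(pairs)
        h = _mode_bandwidth(theta, 1.0)
        est = weighted_mode(pairs, n_boot=30, seed=4)
        assert abs(est.beta - 0.3) < h

    def test_requires_three_pairs(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_mode(make_pairs([0.1, 0.2], [0.02, 0.04], [0.01, 0.01]))


class TestCochranQ:
    def test_hand_arithmetic(self):
        # unit weights, ratios {0, 1}, pooled 0.5 -> Q = 0.5
        pairs = make_pairs([1.0, 1.0], [0.0, 1.0], [1.0, 1.0])
        pooled = ivw(pairs, random_effects=False)
        assert pooled.beta == pytest.approx(0.5)
        q, df, _ = cochran_q(pairs, pooled)
        assert q == pytest.approx(0.5) and df == 1

    def test_matches_brute_force_summation(self, rng):
        bx = rng.normal(0.25, 0.05, 15)
        by = 0.1 * bx + rng.normal(0, 0.02, 15)
        sy = rng.uniform(0.01, 0.04, 15)
        pairs = make_pairs(bx, by, sy)
        pooled = ivw(pairs)
        q, df, _ = cochran_q(pairs, pooled)
        brute = sum(
            (x**2 / s**2) * (y / x - pooled.beta) ** 2
            for x, y, s in zip(bx, by, sy)
        )
        assert q == pytest.approx(brute, rel=1e-12)
        assert q >= 0

    def test_invariant_to_instrument_ordering(self, rng):
        bx = rng.normal(0.25, 0.05, 8)
        by = 0.1 * bx + rng.normal(0, 0.02, 8)
        sy = rng.uniform(0.01, 0.04, 8)
        pairs = make_pairs(bx, by, sy)
        pooled = ivw(pairs)
        q1, _, _ = cochran_q(pairs, pooled)
        q2, _, _ = cochran_q(list(reversed(pairs)), pooled)
        assert q1 == pytest.approx(q2)


class TestLeaveOneOut:
    def test_identical_pairs_identical_estimates(self):
        pairs = make_pairs([0.2] * 5, [0.06] * 5, [0.01] * 5)
        table = leave_one_out(pairs)
        assert len(table) == 5
        assert np.allclose(table["beta"], 0.3)

    def test_gross_outlier_most_influential(self, rng):
        bx = np.concatenate([rng.normal(0.3, 0.02, 9), [0.3]])
        by = np.concatenate([0.2 * bx[:9] + rng.normal(0, 0.002, 9), [0.9]])
        pairs = make_pairs(bx, by, [0.01] * 10)
        full = ivw(pairs)
        table = leave_one_out(pairs)
        deltas = (table["beta"] - full.beta).abs()
        assert deltas.idxmax() == "rs10"


class TestORConversions:
    def test_published_worked_example(self):
        orv, lo, hi = or_from_beta(0.173, 0.048)
        assert round(orv, 3) == 1.189
        assert round(lo, 3) == 1.082
        assert round(hi, 3) == 1.306

    def test_null_beta_symmetric_ci(self):
        orv, lo, hi = or_from_beta(0.0, 0.1)
        assert orv == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)

    def test_round_trip_recovers_se(self, rng):
        for _ in range(20):
            beta = float(rng.normal(0, 0.5))
            se = float(rng.uniform(0.01, 0.5))
            orv, lo, hi = or_from_beta(beta, se)
            se_back, _, _ = p_from_or_ci(max(orv, lo), min(lo, orv), max(hi, orv))
            assert se_back == pytest.approx(se, abs=1e-9)

    def test_p_recovery_published_examples(self):
        _, _, p = p_from_or_ci(1.230, 1.040, 1.455)
        assert round(p, 3) == 0.016
        _, _, p2 = p_from_or_ci(1.449, 1.168, 1.797)
        assert p2 < 0.001

    def test_null_or_gives_p_one(self):
        _, _, p = p_from_or_ci(1.0, 0.5, 2.0)
        assert p == pytest.approx(1.0)

    def test_inconsistent_ci_rejected(self):
        with pytest.raises(ValueError):
            p_from_or_ci(1.2, 1.3, 1.5)


class TestEstimatorAgreement:
    def test_all_estimators_agree_without_pleiotropy(self, rng):
        # clean generator: no pleiotropy, homogeneous ratio, tight noise
        k = 50
        bx = rng.normal(0.3, 0.05, k)
        sy = np.full(k, 0.005)
        by = 0.15 * bx + rng.normal(0, 0.005, k)
        pairs = make_pairs(bx, by, sy)
        betas = [
            ivw(pairs).beta,
            egger(pairs)[0].beta,
            weighted_median(pairs, n_boot=30, seed=5).beta,
            weighted_mode(pairs, n_boot=30, seed=5).beta,
        ]
        assert max(betas) - min(betas) < 0.05
        assert all(abs(b - 0.15) < 0.05 for b in betas)


class TestModelFacade:
    def test_fit_all_table(self, rng):
        bx = rng.normal(0.3, 0.05, 10)
        by = 0.15 * bx + rng.normal(0, 0.01, 10)
        pairs = make_pairs(bx, by, [0.01] * 10)
        model = MRModel(pairs, exposure="DPF2", outcome="COAD")
        table = model.fit_all(seed=1)
        assert set(table["method"]) == {"ivw", "egger", "weighted_median", "weighted_mode"}
        assert (table["nsnp"] == 10).all()

    def test_summary_contains_or_and_ci(self, rng):
        bx = rng.normal(0.3, 0.05, 5)
        by = 0.15 * bx + rng.normal(0, 0.01, 5)
        res = MRModel(make_pairs(bx, by, [0.01] * 5)).fit("ivw")
        text = res.summary()
        assert "OR" in text and "ivw" in text

    def test_sensitivity_report_shapes(self, rng):
        bx = rng.normal(0.3, 0.05, 8)
        by = 0.15 * bx + rng.normal(0, 0.01, 8)
        model = MRModel(make_pairs(bx, by, [0.01] * 8))
        rep = model.sensitivity()
        assert rep.q_df == 7
        assert len(rep.leave_one_out) == 8
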