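import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cismr.errors import EstimationError
from cismr.estimators import (
    all_estimates,
    cochran_q,
    ivw_mre,
    leave_one_out,
    mr_egger,
    to_odds_ratio,
    wald_ratios,
    weighted_median,
    weighted_median_point,
    weighted_mode,
    weighted_mode_point,
)
from conftest import make_pairs


class TestWaldRatios:
    def test_hand_arithmetic(self):
        (r,) = wald_ratios(make_pairs([0.5], [0.25], [0.1]))
        assert r.ratio == pytest.approx(0.5)
        assert r.ratio_se == pytest.approx(0.2)

    def test_negative_exposure_beta(self):
        (r,) = wald_ratios(make_pairs([-0.5], [0.25], [0.1]))
        assert r.ratio == pytest.approx(-0.5)
        assert r.ratio_se == pytest.approx(0.2)  # se stays positive

    def test_null_numerator(self):
        (r,) = wald_ratios(make_pairs([0.5], [0.0], [0.1]))
        assert r.ratio == 0.0
        assert r.ratio_se == pytest.approx(0.2)

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(EstimationError, match="rs0"):
            wald_ratios(make_pairs([0.0], [0.1], [0.1]))


class TestIVW:
    def test_derived_equal_weight_mean(self):
        est = ivw_mre(make_pairs([1.0, 1.0], [0.5, 0.3], [0.1, 0.1]))
        assert est.beta == pytest.approx(0.4)

    def test_perfect_fit_floors_dispersion(self):
        pairs = make_pairs([1.0, 2.0, 3.0], [0.5, 1.0, 1.5], [0.1, 0.1, 0.1])
        est = ivw_mre(pairs)
        assert est.beta == pytest.approx(0.5)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)
        # dispersion floored at 1: se equals the fixed-effect se
        fixed_se = math.sqrt(1.0 / sum((g / 0.1) ** 2 for g in (1, 2, 3)))
        assert est.se == pytest.approx(fixed_se)

    def test_duplicated_single_pair(self):
        pairs = make_pairs([0.5, 0.5], [0.25, 0.25], [0.1, 0.1])
        est = ivw_mre(pairs)
        assert est.beta == pytest.approx(0.5)

    def test_requires_two_pairs(self):
        with pytest.raises(EstimationError, match="wald_ratios"):
            ivw_mre(make_pairs([1.0], [0.5], [0.1]))

    def test_ci_brackets_beta(self):
        est = ivw_mre(make_pairs([1.0, 1.0, 2.0], [0.5, 0.2, 0.9], [0.1, 0.2, 0.1]))
        assert est.ci_low <= est.beta <= est.ci_high

    @given(
        g=arrays(float, 5, elements=st.floats(0.05, 2.0)),
        G=arrays(float, 5, elements=st.floats(-1.0, 1.0)),
        sy=arrays(float, 5, elements=st.floats(0.01, 0.5)),
    )
    @settings(max_examples=100, deadline=None)
    def test_equals_weighted_mean_of_wald_ratios(self, g, G, sy):
        pairs = make_pairs(g, G, sy)
        est = ivw_mre(pairs)
        ratios = wald_ratios(pairs)
        weights = np.array([r.weight for r in ratios])
        mean = np.sum(weights * [r.ratio for r in ratios]) / weights.sum()
        assert est.beta == pytest.approx(mean, abs=1e-12)

    @given(
        g=arrays(float, 6, elements=st.floats(0.05, 2.0)),
        G=arrays(float, 6, elements=st.floats(-1.0, 1.0)),
        flip=arrays(bool, 6),
    )
    @settings(max_examples=50, deadline=None)
    def test_sign_flip_invariance(self, g, G, flip):
        sy = np.full(6, 0.1)
        sign = np.where(flip, -1.0, 1.0)
        a = ivw_mre(make_pairs(g, G, sy))
        b = ivw_mre(make_pairs(sign * g, sign * G, sy))
        assert a.beta == pytest.approx(b.beta, rel=1e-10)
        assert a.se == pytest.approx(b.se, rel=1e-10)


class TestCochranQ:
    def test_identical_ratios(self):
        q, p = cochran_q(make_pairs([1.0, 2.0], [0.5, 1.0], [0.1, 0.1]))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        g = [1.0, 2.0, 0.5]
        G = [0.5, 0.8, 0.1]
        sy = [0.1, 0.2, 0.05]
        # independent sum-of-squares computation from first principles
        ratios = [G[i] / g[i] for i in range(3)]
        weights = [(g[i] / sy[i]) ** 2 for i in range(3)]
        beta_fixed = sum(w * r for w, r in zip(weights, ratios)) / sum(weights)
        q_expected = sum(w * (r - beta_fixed) ** 2
                         for w, r in zip(weights, ratios))
        q, _ = cochran_q(make_pairs(g, G, sy))
        assert q == pytest.approx(q_expected, rel=1e-12)

    def test_doubling_sigma_quarters_q(self):
        g, G = [1.0, 1.0, 2.0], [0.5, 0.2, 0.9]
        sy = np.array([0.1, 0.2, 0.15])
        q1, _ = cochran_q(make_pairs(g, G, sy))
        q2, _ = cochran_q(make_pairs(g, G, 2 * sy))
        assert q2 == pytest.approx(q1 / 4, rel=1e-12)

    def test_requires_two_pairs(self):
        with pytest.raises(EstimationError):
            cochran_q(make_pairs([1.0], [0.5], [0.1]))


class TestEgger:
    def test_derived_collinear_exact_fit(self):
        pairs = make_pairs([1.0, 2.0, 3.0], [0.6, 1.1, 1.6], [0.1, 0.1, 0.1])
        est = mr_egger(pairs)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.1, abs=1e-10)
        assert est.q_stat == pytest.approx(0.0, abs=1e-16)  # RSS of exact fit

    def test_proportional_effects_zero_intercept(self):
        pairs = make_pairs([1.0, 2.0, 3.0, 4.0], [0.3, 0.6, 0.9, 1.2],
                           [0.1, 0.1, 0.1, 0.1])
        est = mr_egger(pairs)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-10)
        assert est.beta == pytest.approx(0.3, abs=1e-10)

    def test_constant_shift_moves_intercept_only(self):
        g = [0.5, 1.0, 1.5, 2.5]
        G = [0.2, 0.35, 0.8, 1.1]
        sy = [0.1, 0.12, 0.08, 0.1]
        base = mr_egger(make_pairs(g, G, sy))
        shifted = mr_egger(make_pairs(g, [x + 0.25 for x in G], sy))
        assert shifted.beta == pytest.approx(base.beta, abs=1e-10)
        assert shifted.egger_intercept == \
            pytest.approx(base.egger_intercept + 0.25, abs=1e-10)

    def test_orients_negative_exposure_betas(self):
        g = np.array([0.5, -1.0, 1.5, -2.5])
        G = np.array([0.2, -0.35, 0.8, -1.1])
        sy = np.full(4, 0.1)
        a = mr_egger(make_pairs(g, G, sy))
        b = mr_egger(make_pairs(np.abs(g), np.sign(g) * G, sy))
        assert a.beta == pytest.approx(b.beta, rel=1e-10)

    def test_requires_three_pairs(self):
        with pytest.raises(EstimationError):
            mr_egger(make_pairs([1.0, 2.0], [0.5, 1.0], [0.1, 0.1]))


class TestWeightedMedian:
    def test_derived_equal_weights(self):
        # cumulative midpoints 1/6, 1/2, 5/6 -> interpolation hits middle ratio
        assert weighted_median_point(np.array([0.1, 0.2, 0.3]),
                                     np.ones(3)) == pytest.approx(0.2)

    def test_dominant_weight_controls_estimate(self):
        ratios = np.array([0.0, 10.0, 20.0])
        weights = np.array([0.2, 0.6, 0.2])
        assert weighted_median_point(ratios, weights) == pytest.approx(10.0)
        # replacing the outlier leaves the estimate unchanged
        assert weighted_median_point(np.array([0.0, 10.0, 1e6]),
                                     weights) == pytest.approx(10.0)

    def test_equal_weights_match_interpolated_median(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ratios = rng.normal(size=7)
            est = weighted_median_point(ratios, np.ones(7))
            assert est == pytest.approx(np.median(ratios), abs=1e-12)

    def test_all_ratios_equal(self):
        pairs = make_pairs([1.0, 2.0, 3.0], [0.5, 1.0, 1.5], [0.1, 0.1, 0.1])
        est = weighted_median(pairs, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.5)
        assert est.se < 0.05  # bootstrap noise only

    def test_estimator_interface(self):
        pairs = make_pairs([1.0, 1.5, 2.0, 0.5], [0.4, 0.7, 0.9, 0.2],
                           [0.1, 0.1, 0.1, 0.1])
        est = weighted_median(pairs, n_boot=500, seed=42)
        assert est.n_snps == 4
        assert est.ci_low <= est.beta <= est.ci_high
        # deterministic under fixed seed
        again = weighted_median(pairs, n_boot=500, seed=42)
        assert again.se == est.se

    def test_requires_three_pairs(self):
        with pytest.raises(EstimationError):
            weighted_median(make_pairs([1.0, 2.0], [0.5, 1.0], [0.1, 0.1]),
                            seed=0)


class TestWeightedMode:
    def test_derived_cluster_mode_ignores_outlier(self):
        ratios = np.array([0.5, 0.5, 0.5, 5.0])
        est = weighted_mode_point(ratios, np.ones(4))
        assert abs(est - 0.5) < abs(est - 5.0)
        assert est == pytest.approx(0.5, abs=0.5)

    def test_tight_cluster(self):
        ratios = np.array([0.49, 0.5, 0.51, 0.5])
        est = weighted_mode_point(ratios, np.ones(4))
        assert est == pytest.approx(0.5, abs=0.02)

    def test_derived_weighted_bimodal(self):
        # grid-oracle: symmetric clusters, weights favor the lower one
        ratios = np.array([-1.0, -1.05, -0.95, 1.0, 1.05, 0.95])
        weights = np.array([3.0, 3.0, 3.0, 1.0, 1.0, 1.0])
        est = weighted_mode_point(ratios, weights, bandwidth_factor=0.5)
        assert est == pytest.approx(-1.0, abs=0.2)

    def test_identical_ratios(self):
        assert weighted_mode_point(np.array([0.7, 0.7, 0.7]),
                                   np.ones(3)) == pytest.approx(0.7)

    def test_estimator_interface(self):
        pairs = make_pairs([1.0, 1.5, 2.0, 0.5], [0.4, 0.7, 0.9, 0.2],
                           [0.1, 0.1, 0.1, 0.1])
        est = weighted_mode(pairs, n_boot=300, seed=9)
        assert est.method == "WeightedMode"
        assert est.ci_low <= est.beta <= est.ci_high

    def test_requires_three_pairs(self):
        with pytest.raises(EstimationError):
            weighted_mode(make_pairs([1.0, 2.0], [0.5, 1.0], [0.1, 0.1]),
                          seed=0)


class TestLeaveOneOut:
    def test_cardinality_and_order(self):
        pairs = make_pairs([1.0, 1.5, 2.0, 0.5], [0.4, 0.7, 0.9, 0.2],
                           [0.1, 0.1, 0.1, 0.1])
        loo = leave_one_out(pairs)
        assert [snp for snp, _ in loo] == [p.snp_id for p in pairs]

    def test_homogeneous_effects_stable(self):
        g = np.linspace(0.5, 2.0, 6)
        pairs = make_pairs(g, 0.4 * g, np.full(6, 0.05))
        loo = leave_one_out(pairs)
        betas = [est.beta for _, est in loo]
        for _, est in loo:
            assert all(est.ci_low <= b <= est.ci_high for b in betas)

    def test_outlier_omission_shifts_most(self):
        g = np.array([1.0, 1.2, 0.8, 1.1, 0.9, 1.0])
        G = 0.5 * g
        G[3] = 3.0  # gross outlier
        pairs = make_pairs(g, G, np.full(6, 0.1))
        full = ivw_mre(pairs).beta
        loo = leave_one_out(pairs)
        shifts = [abs(est.beta - full) for _, est in loo]
        assert int(np.argmax(shifts)) == 3
        # verified by direct recomputation without the outlier
        direct = ivw_mre([p for i, p in enumerate(pairs) if i != 3]).beta
        assert loo[3][1].beta == pytest.approx(direct, rel=1e-12)

    def test_requires_three_pairs(self):
        with pytest.raises(EstimationError):
            leave_one_out(make_pairs([1.0, 2.0], [0.5, 1.0], [0.1, 0.1]))


class TestOddsRatio:
    def test_null_effect(self):
        est = ivw_mre(make_pairs([1.0, 1.0], [0.0, 0.0], [0.1, 0.1]))
        assert to_odds_ratio(est).or_ == pytest.approx(1.0)

    def test_derived_exp(self):
        est = ivw_mre(make_pairs([1.0, 1.0], [-0.673, -0.673], [0.1, 0.1]))
        assert to_odds_ratio(est).or_ == pytest.approx(math.exp(-0.673))
        assert to_odds_ratio(est).or_ == pytest.approx(0.51, abs=0.005)

    def test_ci_order_preserved(self):
        est = ivw_mre(make_pairs([1.0, 1.0, 2.0], [0.5, 0.2, 0.9],
                                 [0.1, 0.2, 0.1]))
        oest = to_odds_ratio(est)
        assert oest.or_ci_low < oest.or_ < oest.or_ci_high


class TestAllEstimates:
    def test_four_methods_on_or_scale(self):
        pairs = make_pairs([1.0, 1.5, 2.0, 0.5, 1.2], [0.4, 0.7, 0.9, 0.2, 0.5],
                           [0.1, 0.1, 0.1, 0.1, 0.1])
        estimates = all_estimates(pairs, n_boot=100, seed=5)
        assert set(estimates) == {"IVW-MRE", "Egger", "WeightedMedian",
                                  "WeightedMode"}
        for est in estimates.values():
            assert est.or_ == pytest.approx(math.exp(est.beta))
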