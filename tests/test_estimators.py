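"""Wald ratio, IVW, MR-Egger, and weighted-median estimators."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from mrmediate.estimators import (
    EggerEstimator,
    IVWEstimator,
    MrResult,
    WeightedMedianEstimator,
    egger,
    ivw,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)

from conftest import make_pairs

Z = 1.959963984540054


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx, sx, by, sy, theta, se",
        [
            (0.1, 0.01, 0.0, 0.005, 0.0, 0.05),
            (0.2, 0.01, 0.2, 0.01, 1.0, 0.05),
            (0.1, 0.01, 0.02, 0.005, 0.2, 0.05),
            (-0.1, 0.01, 0.02, 0.005, -0.2, 0.05),
        ],
    )
    def test_delta_method_arithmetic(self, bx, sx, by, sy, theta, se):
        got_theta, got_se = wald_ratio(bx, sx, by, sy)
        assert got_theta == pytest.approx(theta)
        assert got_se == pytest.approx(se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.01)


class TestIVW:
    def test_equal_precision_gives_plain_mean(self):
        pairs = make_pairs([1.0, 1.0], [0.1, 0.3], se_y=0.05)
        assert ivw(pairs).beta == pytest.approx(0.2)

    def test_homogeneous_ratios_fixed_equals_random(self):
        pairs = make_pairs([1.0, 2.0, 0.5], [0.7, 1.4, 0.35], se_y=0.05)
        fe = ivw(pairs, effects_model="fixed")
        re = ivw(pairs, effects_model="random")
        assert fe.beta == pytest.approx(0.7)
        assert fe.extra["Q"] == pytest.approx(0.0, abs=1e-20)
        assert fe.se == pytest.approx(re.se)  # Q=0: inflation floored at 1

    def test_weighted_mean_against_closed_form(self):
        # thetas {0.1, 0.2, 0.4}, se_theta {0.05, 0.1, 0.2} => w {400, 100, 25}
        # beta = (400*.1 + 100*.2 + 25*.4)/525 = 2/15; Q = 8/3
        pairs = make_pairs([1.0, 1.0, 1.0], [0.1, 0.2, 0.4], se_y=[0.05, 0.1, 0.2])
        res = ivw(pairs, effects_model="fixed")
        assert res.beta == pytest.approx(2.0 / 15.0, rel=1e-12)
        assert res.se == pytest.approx(math.sqrt(1.0 / 525.0), rel=1e-12)
        assert res.extra["Q"] == pytest.approx(8.0 / 3.0, rel=1e-12)
        assert res.ci_low == pytest.approx(res.beta - Z * res.se)
        assert res.or_ == pytest.approx(math.exp(res.beta))

    def test_single_snp_degenerates_to_wald(self):
        pairs = make_pairs([0.1], [0.02], se_y=0.005)
        res = ivw(pairs)
        assert res.method == "wald"
        theta, se = wald_ratio(0.1, 0.0, 0.02, 0.005)
        assert res.beta == pytest.approx(theta) and res.se == pytest.approx(se)

    def test_auto_switches_to_random_under_heterogeneity(self):
        rng = np.random.default_rng(4)
        theta = rng.normal(0.5, 0.5, 20)
        pairs = make_pairs(np.ones(20), theta, se_y=0.05)
        res = ivw(pairs, effects_model="auto")
        assert res.method == "ivw_re"
        assert res.se > ivw(pairs, effects_model="fixed").se

    @given(st.randoms(use_true_random=False))
    def test_order_and_joint_signflip_invariance(self, rnd):
        rng = np.random.default_rng(rnd.randrange(2**31))
        j = 8
        bx = rng.normal(0.2, 0.1, j)
        bx[bx == 0] = 0.1
        by = rng.normal(0.1, 0.05, j)
        pairs = make_pairs(bx, by, se_y=rng.uniform(0.01, 0.05, j))
        base = ivw(pairs, effects_model="fixed")
        perm = rng.permutation(j)
        flip = np.where(rng.random(j) < 0.5, -1.0, 1.0)
        df = pairs.iloc[perm].reset_index(drop=True)
        df["beta_x"] = df["beta_x"] * flip[perm]
        df["beta_y"] = df["beta_y"] * flip[perm]
        alt = ivw(df, effects_model="fixed")
        assert alt.beta == pytest.approx(base.beta, rel=1e-12)
        assert alt.se == pytest.approx(base.se, rel=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ivw(make_pairs([], []))


class TestEgger:
    def test_noiseless_proportional_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        res = egger(make_pairs(bx, 0.5 * bx, se_y=0.05))
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.extra["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_pleiotropy_recovered_in_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        res = egger(make_pairs(bx, 0.5 * bx + 0.02, se_y=0.05))
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.extra["intercept"] == pytest.approx(0.02, abs=1e-10)

    def test_matches_weighted_normal_equations(self):
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.05, 0.4, 5)
        se_y = rng.uniform(0.02, 0.08, 5)
        by = 0.5 * bx + 0.01 + rng.normal(0, se_y)
        pairs = make_pairs(bx, by, se_y=se_y)
        res = egger(pairs)
        # independent oracle: solve the weighted normal equations directly
        w = 1.0 / se_y**2
        x = np.column_stack([np.ones(5), bx])
        xtwx = x.T @ (w[:, None] * x)
        coef = np.linalg.solve(xtwx, x.T @ (w * by))
        resid = by - x @ coef
        scale = float(resid @ (w * resid) / (5 - 2))
        cov = scale * np.linalg.inv(xtwx)
        assert res.extra["intercept"] == pytest.approx(coef[0], rel=1e-8)
        assert res.beta == pytest.approx(coef[1], rel=1e-8)
        assert res.se == pytest.approx(math.sqrt(cov[1, 1]), rel=1e-8)
        assert res.extra["intercept_se"] == pytest.approx(math.sqrt(cov[0, 0]), rel=1e-8)

    def test_orientation_does_not_change_fit(self):
        rng = np.random.default_rng(12)
        bx = rng.uniform(0.05, 0.4, 6)
        by = 0.5 * bx + rng.normal(0, 0.05, 6)
        pairs = make_pairs(bx, by, se_y=0.05)
        flipped = pairs.copy()
        flipped.loc[:2, "beta_x"] *= -1
        flipped.loc[:2, "beta_y"] *= -1
        a, b = egger(pairs), egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.extra["intercept"] == pytest.approx(b.extra["intercept"], rel=1e-12)

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            egger(make_pairs([0.1, 0.2], [0.05, 0.1]))


class TestWeightedMedian:
    def test_equal_weights_give_plain_median(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [1.0, 2.0, 9.0], se_y=1.0)
        res = weighted_median(pairs, n_boot=200, seed=0)
        assert res.beta == pytest.approx(2.0)

    def test_dominant_weight_pins_estimate(self):
        # middle SNP carries ~98% of the weight
        pairs = make_pairs([1.0, 1.0, 1.0], [1.0, 2.0, 9.0], se_y=[0.7, 0.07, 0.7])
        res = weighted_median(pairs, n_boot=200, seed=0)
        assert res.beta == pytest.approx(2.0, abs=0.15)

    def test_bootstrap_seed_reproducible(self):
        rng = np.random.default_rng(5)
        pairs = make_pairs(rng.uniform(0.1, 0.3, 6), rng.uniform(0.0, 0.2, 6), se_y=0.05)
        a = weighted_median(pairs, n_boot=200, seed=9)
        b = weighted_median(pairs, n_boot=200, seed=9)
        assert a.se == b.se
        assert a.extra["bootstrap_seed"] == 9

    def test_minimum_bootstrap_size_enforced(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [1.0, 2.0, 9.0])
        with pytest.raises(ValueError):
            weighted_median(pairs, n_boot=50)


class TestOddsRatio:
    def test_null_effect_gives_unit_or(self):
        or_, lo, hi, p = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo == pytest.approx(math.exp(-Z * 0.1))
        assert hi == pytest.approx(math.exp(Z * 0.1))
        assert p == pytest.approx(1.0)

    def test_vanishing_se_collapses_ci(self):
        or_, lo, hi, _ = to_odds_ratio(math.log(2), 1e-12)
        assert or_ == pytest.approx(2.0)
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_closed_form_example(self):
        beta, se = -0.286, 0.117
        or_, lo, hi, p = to_odds_ratio(beta, se)
        assert or_ == pytest.approx(math.exp(-0.286), rel=1e-12)
        assert lo == pytest.approx(math.exp(beta - Z * se), rel=1e-9)
        assert hi == pytest.approx(math.exp(beta + Z * se), rel=1e-9)
        assert 0.01 < p < 0.02  # |z| = 2.444

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, 0.0)


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip_and_clone(self):
        est = IVWEstimator(effects_model="fixed")
        assert est.get_params() == {"effects_model": "fixed"}
        c = clone(est)
        assert c.get_params() == est.get_params()
        wm = WeightedMedianEstimator(n_boot=250, seed=3)
        assert clone(wm).get_params() == {"n_boot": 250, "seed": 3}

    def test_fitted_attributes_and_predict(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        est = EggerEstimator().fit(make_pairs(bx, 0.5 * bx + 0.02, se_y=0.05))
        assert est.n_snps_ == 4
        np.testing.assert_allclose(est.predict([0.0, 1.0]), [0.02, 0.52], atol=1e-9)
        ivw_est = IVWEstimator().fit(make_pairs(bx, 0.5 * bx, se_y=0.05))
        np.testing.assert_allclose(ivw_est.predict([1.0]), [0.5], atol=1e-9)

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            MrResult(
                method="ivw_fe", beta=1.0, se=0.1, ci_low=2.0, ci_high=3.0,
                pval=0.5, or_=math.e, or_low=1.0, or_high=2.0, n_snps=2,
            )
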