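import math

import numpy as np
import pytest

from conftest import consensus_insts, make_inst, random_insts
from oracles import weighted_median_oracle, wls_oracle
from tsmr.estimators import (
    MODEL_FIXED,
    MODEL_RANDOM,
    Z_975,
    interpolated_weighted_median,
    ivw,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from tsmr.exceptions import DegenerateDesignError, NotEstimableError


class TestWaldRatio:
    def test_direct_ratio(self):
        est = wald_ratio(make_inst(beta_exp=0.5, beta_out=0.25, se_out=0.1))
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome(self):
        assert wald_ratio(make_inst(beta_out=0.0)).theta == 0.0

    def test_sign_symmetry(self):
        est = wald_ratio(make_inst(beta_exp=-0.5, beta_out=0.25, se_out=0.1))
        assert est.theta == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateDesignError):
            wald_ratio(make_inst(beta_exp=0.0))


class TestIVW:
    def test_consensus_instruments(self):
        insts = [
            make_inst("rs1", beta_exp=0.1, beta_out=0.03, se_out=0.05),
            make_inst("rs2", beta_exp=0.2, beta_out=0.06, se_out=0.11),
        ]
        assert ivw(insts).theta == pytest.approx(0.3)

    def test_single_snp_reduces_to_wald(self):
        inst = make_inst(beta_exp=0.2, beta_out=0.1, se_out=0.07)
        est = ivw([inst])
        w = wald_ratio(inst)
        assert est.theta == pytest.approx(w.theta)
        assert est.se == pytest.approx(w.se)
        assert est.method == "IVW" and est.note

    def test_three_snp_normal_equations_oracle(self):
        insts = [
            make_inst("rs1", beta_exp=0.1, beta_out=0.05, se_out=0.01),
            make_inst("rs2", beta_exp=0.2, beta_out=0.08, se_out=0.02),
            make_inst("rs3", beta_exp=0.15, beta_out=0.09, se_out=0.015),
        ]
        bx = np.array([0.1, 0.2, 0.15])
        by = np.array([0.05, 0.08, 0.09])
        w = 1 / np.array([0.01, 0.02, 0.015]) ** 2
        coefs, cov = wls_oracle(bx, by, w, intercept=False)
        est = ivw(insts, model=MODEL_FIXED)
        assert est.theta == pytest.approx(coefs[0], rel=1e-12)
        assert est.se == pytest.approx(math.sqrt(cov[0, 0]), rel=1e-12)

    def test_oracle_on_random_sets(self, rng):
        for _ in range(30):
            insts = random_insts(rng, int(rng.integers(2, 15)))
            bx = np.array([h.beta_exp for h in insts])
            by = np.array([h.beta_out for h in insts])
            w = 1 / np.array([h.se_out for h in insts]) ** 2
            coefs, cov = wls_oracle(bx, by, w, intercept=False)
            est = ivw(insts, model=MODEL_FIXED)
            assert est.theta == pytest.approx(coefs[0], rel=1e-10)
            assert est.se == pytest.approx(math.sqrt(cov[0, 0]), rel=1e-10)

    def test_fixed_and_random_share_point_estimate(self, rng):
        for _ in range(10):
            insts = random_insts(rng, 8)
            fixed = ivw(insts, model=MODEL_FIXED)
            rand = ivw(insts, model=MODEL_RANDOM)
            assert fixed.theta == rand.theta
            assert rand.se >= fixed.se  # multiplicative scale >= 1

    def test_sign_flip_equivariance(self, rng):
        insts = random_insts(rng, 6)
        flipped = [
            make_inst(h.snp_id, -h.beta_exp, h.se_exp, -h.beta_out, h.se_out) for h in insts
        ]
        assert ivw(flipped).theta == pytest.approx(ivw(insts).theta, rel=1e-12)

    def test_all_zero_exposure_degenerate(self):
        insts = [make_inst(f"rs{i}", beta_exp=0.0) for i in range(3)]
        with pytest.raises(DegenerateDesignError):
            ivw(insts)

    def test_empty_not_estimable(self):
        with pytest.raises(NotEstimableError):
            ivw([])


class TestMREgger:
    def test_exact_linear_fit(self):
        # points generated exactly as by = 0.1 + 0.4 * bx, equal weights
        xs = [0.1, 0.2, 0.3, 0.4]
        insts = [
            make_inst(f"rs{i}", beta_exp=x, beta_out=0.1 + 0.4 * x, se_out=0.05)
            for i, x in enumerate(xs)
        ]
        est, fit = mr_egger(insts)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        assert fit.slope == pytest.approx(0.4, abs=1e-12)
        assert est.theta == fit.slope

    def test_two_snps_not_estimable(self):
        insts = [make_inst("rs1"), make_inst("rs2", beta_exp=0.2)]
        with pytest.raises(NotEstimableError):
            mr_egger(insts)

    def test_oracle_on_random_sets(self, rng):
        for _ in range(20):
            insts = random_insts(rng, 10)
            bx = np.abs([h.beta_exp for h in insts])
            by = np.array([h.beta_out for h in insts]) * np.sign(
                [h.beta_exp for h in insts]
            )
            w = 1 / np.array([h.se_out for h in insts]) ** 2
            coefs, cov = wls_oracle(bx, by, w, intercept=True)
            resid = by - coefs[0] - coefs[1] * bx
            scale = max(1.0, math.sqrt(float(np.sum(w * resid**2)) / (len(insts) - 2)))
            est, fit = mr_egger(insts)
            assert fit.intercept == pytest.approx(coefs[0], rel=1e-10, abs=1e-14)
            assert fit.slope == pytest.approx(coefs[1], rel=1e-10)
            assert fit.slope_se == pytest.approx(math.sqrt(cov[1, 1]) * scale, rel=1e-10)
            assert fit.intercept_se == pytest.approx(math.sqrt(cov[0, 0]) * scale, rel=1e-10)

    def test_zero_spread_degenerate(self):
        insts = [make_inst(f"rs{i}", beta_exp=0.2, beta_out=0.1) for i in range(4)]
        with pytest.raises(DegenerateDesignError):
            mr_egger(insts)

    def test_sign_flip_equivariance(self, rng):
        insts = random_insts(rng, 8)
        flipped = [
            make_inst(h.snp_id, -h.beta_exp, h.se_exp, -h.beta_out, h.se_out)
            if i % 2
            else h
            for i, h in enumerate(insts)
        ]
        _, fit_a = mr_egger(insts)
        _, fit_b = mr_egger(flipped)
        assert fit_b.slope == pytest.approx(fit_a.slope, rel=1e-12)
        assert fit_b.intercept == pytest.approx(fit_a.intercept, rel=1e-12)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        insts = [
            make_inst(f"rs{i}", beta_exp=0.1, beta_out=0.1 * r, se_out=0.05)
            for i, r in enumerate([0.1, 0.2, 0.3])
        ]
        est = weighted_median(insts, n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            insts = random_insts(rng, 5)
            est = weighted_median(insts, n_boot=10, seed=0)
            ratios = [h.beta_out / h.beta_exp for h in insts]
            weights = [h.beta_exp**2 / h.se_out**2 for h in insts]
            assert est.theta == pytest.approx(weighted_median_oracle(ratios, weights), rel=1e-12)

    def test_dominant_weight_limit(self):
        # as one instrument's weight tends to 1 the estimate tends to its ratio
        ratios = np.array([1.0, 2.0, 3.0])
        for wt, tol in [(0.6, 0.6), (0.99, 0.03), (0.9999, 3e-4)]:
            w = np.array([wt, (1 - wt) / 2, (1 - wt) / 2])
            assert abs(interpolated_weighted_median(ratios, w) - 1.0) < tol

    def test_equal_weights_equals_plain_interpolated_median(self, rng):
        vals = rng.normal(size=7)
        w = np.ones(7)
        order = np.sort(vals)
        cum = (np.arange(7) + 0.5) / 7
        assert interpolated_weighted_median(vals, w) == pytest.approx(
            float(np.interp(0.5, cum, order))
        )

    def test_bootstrap_reproducible_and_stable(self, rng):
        insts = random_insts(rng, 10)
        a = weighted_median(insts, n_boot=1000, seed=42)
        b = weighted_median(insts, n_boot=1000, seed=42)
        assert a.se == b.se
        c = weighted_median(insts, n_boot=1000, seed=7)
        assert abs(c.se - a.se) / a.se < 0.10

    def test_too_few_instruments(self):
        with pytest.raises(NotEstimableError):
            weighted_median([make_inst("rs1"), make_inst("rs2")], seed=0)


class TestOddsRatio:
    def test_null_effect(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_narrow_ci_limit(self):
        or_, lo, hi = to_odds_ratio(math.log(2), 1e-12)
        assert or_ == pytest.approx(2.0)
        assert lo == pytest.approx(2.0, abs=1e-9)
        assert hi == pytest.approx(2.0, abs=1e-9)

    def test_frozen_values(self):
        or_, lo, hi = to_odds_ratio(0.5, 0.25)
        assert or_ == pytest.approx(1.6487, abs=1e-4)
        assert lo == pytest.approx(1.0101, abs=1e-4)
        assert hi == pytest.approx(2.6912, abs=1e-4)

    def test_estimate_invariants(self, rng):
        for _ in range(10):
            est = ivw(random_insts(rng, 6))
            assert est.ci_low < est.or_ < est.ci_high
            assert est.or_ == pytest.approx(math.exp(est.theta), rel=1e-15)
            assert est.ci_low == pytest.approx(math.exp(est.theta - Z_975 * est.se), rel=1e-15)
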