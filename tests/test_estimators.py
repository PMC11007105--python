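"""The five causal-effect estimators against hand computations and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.errors import EstimationError
from mrkit.estimators import (
    egger,
    ivw,
    max_likelihood,
    to_odds_ratio,
    wald_ratios,
    weighted_median,
)
from mrkit.gwas_io import harmonize
from mrkit.synthetic import SimConfig, simulate_pair

from _oracles import oracle_egger, oracle_ivw, oracle_weighted_median


class TestWaldRatios:
    def test_delta_method_example(self, make_harmonized):
        h = make_harmonized([0.2], [0.1], [0.05])
        ratio, ratio_se, _ = wald_ratios(h)
        assert ratio[0] == pytest.approx(0.5)
        assert ratio_se[0] == pytest.approx(0.25)

    def test_zero_outcome_beta(self, make_harmonized):
        h = make_harmonized([0.2], [0.0], [0.05])
        ratio, ratio_se, _ = wald_ratios(h)
        assert ratio[0] == 0.0 and ratio_se[0] == pytest.approx(0.25)

    def test_joint_sign_flip_invariance(self, make_harmonized):
        h1 = make_harmonized([0.2, 0.3], [0.1, 0.2], [0.05, 0.05])
        h2 = make_harmonized([-0.2, -0.3], [-0.1, -0.2], [0.05, 0.05])
        np.testing.assert_allclose(wald_ratios(h1)[0], wald_ratios(h2)[0])

    def test_zero_exposure_beta_excluded(self, make_harmonized):
        h = make_harmonized([0.2, 0.0], [0.1, 0.1], [0.05, 0.05])
        ratio, _, used = wald_ratios(h)
        assert ratio.size == 1 and used.tolist() == [True, False]


class TestIvw:
    def test_worked_example_and_oracle(self, make_harmonized):
        # unit exposure betas make Wald ratios (0.1, 0.2) with ratio se 0.05
        h = make_harmonized([1.0, 1.0], [0.1, 0.2], [0.05, 0.05])
        fe = ivw(h, model="fixed")
        mre = ivw(h, model="mre")
        assert fe.beta == pytest.approx(0.15)
        assert fe.se == pytest.approx(math.sqrt(1 / 800), abs=1e-6)  # 0.03536
        assert mre.extra["q"] == pytest.approx(2.0)
        assert mre.se == pytest.approx(0.05, abs=1e-6)
        ob, ose, oq = oracle_ivw(h.beta_exp, h.beta_out, h.se_out)
        assert (fe.beta, fe.se, mre.extra["q"]) == pytest.approx((ob, ose, oq))

    def test_homogeneous_ratios_give_zero_q(self, make_harmonized):
        h = make_harmonized([1.0, 2.0, 0.5], [0.3, 0.6, 0.15], [0.05, 0.05, 0.05])
        mre = ivw(h, model="mre")
        assert mre.beta == pytest.approx(0.3)
        assert mre.extra["q"] == pytest.approx(0.0, abs=1e-20)
        assert mre.se == pytest.approx(ivw(h, model="fixed").se)

    def test_duplicating_snps_halves_fixed_variance(self, make_harmonized):
        h1 = make_harmonized([1.0, 1.0], [0.1, 0.2], [0.05, 0.05])
        h2 = make_harmonized([1.0, 1.0] * 2, [0.1, 0.2] * 2, [0.05, 0.05] * 2)
        assert ivw(h2, "fixed").se**2 == pytest.approx(ivw(h1, "fixed").se**2 / 2)

    def test_mre_se_never_below_fixed(self, make_harmonized):
        rng = np.random.default_rng(3)
        for _ in range(50):
            J = rng.integers(2, 12)
            h = make_harmonized(
                rng.uniform(0.05, 0.5, J), rng.normal(0, 0.1, J), rng.uniform(0.01, 0.2, J)
            )
            assert ivw(h, "mre").se >= ivw(h, "fixed").se - 1e-15

    def test_insufficient_instruments(self, make_harmonized):
        with pytest.raises(EstimationError):
            ivw(make_harmonized([0.2], [0.1], [0.05]))


class TestEgger:
    def test_exact_line_through_collinear_points(self, make_harmonized):
        h = make_harmonized([0.1, 0.2, 0.3], [0.06, 0.11, 0.16], [0.05] * 3)
        est = egger(h)
        assert est.beta == pytest.approx(0.5)
        assert est.extra["intercept"] == pytest.approx(0.01)
        oi, osl = oracle_egger(h.beta_exp, h.beta_out, h.se_out)
        assert (est.extra["intercept"], est.beta) == pytest.approx((oi, osl))

    def test_outcome_shift_moves_intercept_not_slope(self, make_harmonized):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.1, 0.4, 8)
        by = 0.3 * bx + rng.normal(0, 0.01, 8)
        se = rng.uniform(0.02, 0.08, 8)
        base = egger(make_harmonized(bx, by, se))
        shifted = egger(make_harmonized(bx, by + 0.05, se))
        assert shifted.beta == pytest.approx(base.beta)
        assert shifted.extra["intercept"] == pytest.approx(base.extra["intercept"] + 0.05)

    def test_balanced_pleiotropy_intercept_covers_zero(self):
        """Zero mean pleiotropy: intercept within 2 SE of 0 in >= 93% of replicates."""
        seeds = np.random.SeedSequence(41).generate_state(300) & 0x7FFFFFFF
        hits = 0
        for s in seeds:
            cfg = SimConfig(seed=int(s), causal_beta=0.15, prop_invalid=1.0,
                            pleiotropy_mean=0.0, pleiotropy_sd=0.05)
            e, o, _ = simulate_pair(cfg)
            h = harmonize(e, o, n_exp=cfg.n_exp, n_out=cfg.n_out)
            est = egger(h)
            hits += abs(est.extra["intercept"]) <= 2 * est.extra["intercept_se"]
        assert hits / len(seeds) >= 0.93

    def test_slope_through_origin_equals_ivw(self, make_harmonized):
        """Constraining the Egger intercept to zero recovers the IVW estimate."""
        rng = np.random.default_rng(6)
        bx = rng.uniform(0.1, 0.4, 10)
        by = rng.normal(0.2 * bx, 0.05)
        se = rng.uniform(0.02, 0.08, 10)
        h = make_harmonized(bx, by, se)
        w = 1 / se**2
        slope_origin = np.sum(w * bx * by) / np.sum(w * bx * bx)
        assert slope_origin == pytest.approx(ivw(h, "fixed").beta)

    def test_insufficient_instruments(self, make_harmonized):
        with pytest.raises(EstimationError):
            egger(make_harmonized([0.1, 0.2], [0.05, 0.1], [0.05, 0.05]))


class TestWeightedMedian:
    def test_equal_weights_interpolates_middle(self, make_harmonized):
        h = make_harmonized([1.0] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2)
        assert est.beta == pytest.approx(
            oracle_weighted_median([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
        )

    def test_degenerate_distribution(self, make_harmonized):
        h = make_harmonized([1.0, 2.0, 0.5], [0.3, 0.6, 0.15], [0.001] * 3,
                            se_exp=[1e-6] * 3)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 0.01

    def test_oracle_agreement_random_inputs(self, make_harmonized):
        rng = np.random.default_rng(9)
        for _ in range(100):
            J = int(rng.integers(3, 12))
            ratios = rng.normal(0.2, 0.5, J)
            se = rng.uniform(0.02, 0.3, J)
            h = make_harmonized(np.ones(J), ratios, se)
            mine = weighted_median(h, n_boot=0).beta
            assert mine == pytest.approx(oracle_weighted_median(ratios, 1 / se**2))

    def test_breakdown_resistance_to_forty_percent_invalid(self, make_harmonized):
        """60% of instruments at the true ratio dominate a +5 contaminated 40%."""
        J = 10
        ratios = np.array([0.3] * 6 + [5.3] * 4)
        h = make_harmonized(np.ones(J), ratios, np.full(J, 0.05))
        est = weighted_median(h, n_boot=0)
        assert abs(est.beta - 0.3) < 0.2
        contaminated_mean = ratios.mean()
        assert abs(est.beta - 0.3) < abs(contaminated_mean - 0.3) / 5

    def test_bootstrap_seed_reproducibility(self, make_harmonized):
        h = make_harmonized([1.0] * 5, [0.1, 0.15, 0.2, 0.25, 0.3], [0.05] * 5,
                            se_exp=[0.02] * 5)
        a = weighted_median(h, n_boot=300, seed=7)
        b = weighted_median(h, n_boot=300, seed=7)
        assert a.se == b.se


class TestMaxLikelihood:
    def test_vanishing_exposure_error_equals_ivw_fixed(self, make_harmonized):
        rng = np.random.default_rng(12)
        bx = rng.uniform(0.1, 0.4, 8)
        by = rng.normal(0.25 * bx, 0.03)
        se = rng.uniform(0.02, 0.08, 8)
        h = make_harmonized(bx, by, se, se_exp=np.full(8, 1e-9))
        ml = max_likelihood(h)
        fe = ivw(h, model="fixed")
        assert ml.beta == pytest.approx(fe.beta, abs=1e-6)
        assert ml.se == pytest.approx(fe.se, abs=1e-5)

    def test_noiseless_recovery(self, make_harmonized):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, 0.4 * bx, np.full(4, 0.01), se_exp=np.full(4, 0.01))
        assert max_likelihood(h).beta == pytest.approx(0.4, abs=1e-6)

    def test_outcome_sign_flip_negates_estimate(self, make_harmonized):
        rng = np.random.default_rng(13)
        bx = rng.uniform(0.1, 0.4, 6)
        by = rng.normal(0.3 * bx, 0.02)
        se = rng.uniform(0.02, 0.08, 6)
        sx = rng.uniform(0.01, 0.03, 6)
        plus = max_likelihood(make_harmonized(bx, by, se, se_exp=sx))
        minus = max_likelihood(make_harmonized(bx, -by, se, se_exp=sx))
        assert minus.beta == pytest.approx(-plus.beta, abs=1e-6)


class TestOddsRatio:
    def test_null_effect_interval(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(0.822, abs=5e-4)
        assert hi == pytest.approx(1.217, abs=5e-4)

    def test_degenerate_se(self):
        or_, lo, hi = to_odds_ratio(0.3, 0.0)
        assert lo == or_ == hi == pytest.approx(math.exp(0.3))

    @settings(derandomize=True, max_examples=50)
    @given(beta=st.floats(-3, 3), se=st.floats(0, 1))
    def test_negation_inverts_odds_ratio(self, beta, se):
        or_p, lo_p, hi_p = to_odds_ratio(beta, se)
        or_m, lo_m, hi_m = to_odds_ratio(-beta, se)
        assert or_m == pytest.approx(1 / or_p)
        assert lo_m == pytest.approx(1 / hi_p)
        assert hi_m == pytest.approx(1 / lo_p)


def test_all_five_estimators_recover_truth_with_strong_instruments():
    """Parameter recovery: strong instruments (per-SNP R² = 0.01 at
    n_exp = 2e5, F ≈ 2000), 50 SNPs, causal effect 0.15; each estimator's
    replicate mean lands within 2 Monte-Carlo SEs of the truth."""
    R, b = 200, 0.15
    seeds = np.random.SeedSequence(21).generate_state(R) & 0x7FFFFFFF
    results = {m: [] for m in ("ivw_mre", "ivw_fe", "egger", "weighted_median", "max_likelihood")}
    for s in seeds:
        cfg = SimConfig(seed=int(s), causal_beta=b, n_snps=50,
                        exposure_r2_per_snp=0.01, n_exp=200000, n_out=50000)
        e, o, _ = simulate_pair(cfg)
        h = harmonize(e, o, n_exp=cfg.n_exp, n_out=cfg.n_out)
        results["ivw_mre"].append(ivw(h, "mre").beta)
        results["ivw_fe"].append(ivw(h, "fixed").beta)
        results["egger"].append(egger(h).beta)
        results["weighted_median"].append(weighted_median(h, n_boot=0).beta)
        results["max_likelihood"].append(max_likelihood(h).beta)
    for method, vals in results.items():
        vals = np.asarray(vals)
        mcse = vals.std(ddof=1) / math.sqrt(R)
        assert abs(vals.mean() - b) <= 2 * mcse, f"{method}: {vals.mean():.5f}"
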