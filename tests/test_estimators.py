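import numpy as np
import pytest
import statsmodels.api as sm

from mrforge import (DegenerateInstrumentError, InsufficientInstrumentsError,
                     ivw, mode_estimate, mr_egger, simple_median, to_odds_scale,
                     wald_ratio, weighted_median)
from mrforge.harmonization import HarmonizedPair, HarmonizedSet

from conftest import ratio_set


def random_set(rng, J=20):
    g = rng.normal(0.1, 0.05, J)
    g[np.abs(g) < 1e-3] = 0.05
    return HarmonizedSet.from_arrays(g, rng.uniform(0.005, 0.02, J),
                                     rng.normal(0.02, 0.05, J),
                                     rng.uniform(0.01, 0.05, J))


class TestWaldRatio:
    def pair(self, G=0.2, g=0.1, sy=0.05, sx=0.01):
        return HarmonizedPair("rs1", g, sx, G, sy, eaf=None)

    def test_first_order(self):
        r = wald_ratio(self.pair())
        assert (r.beta_j, r.se_j) == (2.0, 0.5)

    def test_zero_outcome_effect(self):
        r = wald_ratio(self.pair(G=0.0))
        assert (r.beta_j, r.se_j) == (0.0, 0.5)

    def test_second_order_matches_delta_method(self):
        r = wald_ratio(self.pair(), se_order="second")
        # independent delta-method evaluation: Var = sy²/g² + G²sx²/g⁴
        expected = np.sqrt(0.05**2 / 0.1**2 + 0.2**2 * 0.01**2 / 0.1**4)
        assert r.se_j == pytest.approx(expected, rel=1e-12)
        assert r.se_j == pytest.approx(0.5385164807, rel=1e-9)

    def test_zero_gamma_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(self.pair(g=0.0))


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        s = HarmonizedSet.from_arrays([0.1], [0.01], [0.2], [0.05])
        est = ivw(s)
        r = wald_ratio(s.pairs[0])
        assert est.beta == pytest.approx(r.beta_j, abs=1e-15)
        assert est.se == pytest.approx(r.se_j, abs=1e-15)

    def test_two_ratio_closed_form(self):
        est = ivw(ratio_set([1.0, 3.0], [1.0, 1.0]))
        assert est.beta == pytest.approx(2.0, abs=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert est.ci_low == pytest.approx(0.614, abs=5e-4)
        assert est.ci_high == pytest.approx(3.386, abs=5e-4)

    def test_equals_through_origin_wls_oracle(self, rng):
        for _ in range(100):
            s = random_set(rng, J=int(rng.integers(2, 51)))
            g, sx, G, sy = s.arrays()
            oracle = sm.WLS(G, g, weights=1 / sy**2).fit()
            est = ivw(s)
            assert abs(est.beta - oracle.params[0]) < 1e-10

    def test_random_effects_never_narrower_than_fixed(self, rng):
        s = random_set(rng, 30)
        assert ivw(s, "random").se >= ivw(s, "fixed").se

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(HarmonizedSet.from_arrays([], [], [], []))


class TestEgger:
    def test_noise_free_interpolation_exact(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        s = HarmonizedSet.from_arrays(g, np.full(4, 1e-12),
                                      0.02 + 0.5 * g, np.full(4, 0.03))
        slope, intercept = mr_egger(s)
        assert slope.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept.beta == pytest.approx(0.02, abs=1e-10)

    def test_matches_wls_regression_oracle(self, rng):
        g = rng.uniform(0.05, 0.3, 15)
        G = rng.normal(0.4 * g, 0.02)
        sy = rng.uniform(0.01, 0.05, 15)
        s = HarmonizedSet.from_arrays(g, np.full(15, 0.01), G, sy)
        slope, intercept = mr_egger(s)
        oracle = sm.WLS(G, sm.add_constant(g), weights=1 / sy**2).fit()
        assert abs(slope.beta - oracle.params[1]) < 1e-10
        assert abs(intercept.beta - oracle.params[0]) < 1e-10

    def test_orientation_makes_fit_sign_invariant(self, rng):
        s = random_set(rng, 12)
        g, sx, G, sy = s.arrays()
        flip = np.where(rng.random(12) < 0.5, -1, 1)
        s2 = HarmonizedSet.from_arrays(g * flip, sx, G * flip, sy)
        a, b = mr_egger(s), mr_egger(s2)
        assert a[0].beta == pytest.approx(b[0].beta, rel=1e-12)
        assert a[1].beta == pytest.approx(b[1].beta, rel=1e-12)

    def test_degenerate_design_rejected(self):
        s = HarmonizedSet.from_arrays([0.1] * 4, [0.01] * 4,
                                      [0.05, 0.04, 0.06, 0.05], [0.02] * 4)
        with pytest.raises(Exception, match="identifiable|identical"):
            mr_egger(s)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(ratio_set([1, 2], [1, 1]))


class TestMedians:
    def test_equal_weights_give_plain_median(self):
        est = weighted_median(ratio_set([1, 2, 3], [1, 1, 1]), n_boot=50, seed=1)
        assert est.beta == pytest.approx(2.0, abs=1e-12)

    def test_weighted_interpolation_hand_walk(self):
        # weights ∝ {1, 2, 1}: cumulative midpoints {0.125, 0.5, 0.875}
        ses = [1.0, 1 / np.sqrt(2), 1.0]
        est = weighted_median(ratio_set([1.0, 2.0, 100.0], ses), n_boot=50, seed=1)
        assert est.beta == pytest.approx(2.0, abs=1e-12)

    def test_simple_median_even_count_interpolates(self):
        est = simple_median(ratio_set([1, 2, 3, 4], [1, 1, 1, 1]),
                            n_boot=50, seed=1)
        assert est.beta == pytest.approx(2.5, abs=1e-12)

    def test_bootstrap_se_reproducible(self):
        s = ratio_set([1.0, 1.5, 2.0, 2.5], [1, 1, 1, 1])
        a = weighted_median(s, n_boot=200, seed=7)
        b = weighted_median(s, n_boot=200, seed=7)
        assert a.se == b.se


class TestMode:
    def test_dominant_cluster(self):
        est = mode_estimate(ratio_set([2, 2, 2, 7], [1, 1, 1, 1]),
                            n_boot=50, seed=1)
        assert est.beta == pytest.approx(2.0, abs=0.05)

    def test_all_identical_returns_common_ratio(self):
        est = mode_estimate(ratio_set([1.5, 1.5, 1.5], [1, 1, 1]),
                            n_boot=50, seed=1)
        assert est.beta == 1.5

    def test_weighted_mode_tracks_heavy_cluster(self):
        # bimodal ratios; weights favour the cluster at 1
        betas = [1.0, 1.01, 0.99, 5.0, 5.01]
        ses = [1 / np.sqrt(0.3)] * 3 + [1 / np.sqrt(0.05)] * 2
        est = mode_estimate(ratio_set(betas, ses), weighted=True,
                            n_boot=50, seed=1)
        assert est.beta == pytest.approx(1.0, abs=0.1)


class TestEquivariance:
    def test_negating_outcomes_negates_all_estimators(self, rng):
        s = random_set(rng, 15)
        g, sx, G, sy = s.arrays()
        neg = HarmonizedSet.from_arrays(g, sx, -G, sy)
        for fn in (lambda x: ivw(x), lambda x: mr_egger(x)[0]):
            a, b = fn(s), fn(neg)
            assert b.beta == pytest.approx(-a.beta, rel=1e-9)
            assert b.se == pytest.approx(a.se, rel=1e-9)
        a = weighted_median(s, n_boot=400, seed=3)
        b = weighted_median(neg, n_boot=400, seed=3)
        assert b.beta == pytest.approx(-a.beta, rel=1e-9)
        # bootstrap SEs agree in distribution, not draw for draw
        assert b.se == pytest.approx(a.se, rel=0.3)

    def test_exposure_rescaling_divides_estimates(self, rng):
        s = random_set(rng, 15)
        g, sx, G, sy = s.arrays()
        c = 3.7
        scaled = HarmonizedSet.from_arrays(c * g, c * sx, G, sy)
        assert ivw(scaled).beta == pytest.approx(ivw(s).beta / c, rel=1e-12)
        a = weighted_median(s, n_boot=100, seed=3).beta
        b = weighted_median(scaled, n_boot=100, seed=3).beta
        assert b == pytest.approx(a / c, rel=1e-9)


class TestOddsScale:
    def test_exponentiation(self):
        from mrforge.estimators import MREstimate
        est = MREstimate("ivw_fixed", 0.0, 0.05, -0.1, 0.1, 1.0, 10)
        out = to_odds_scale(est, "binary")
        assert out.or_scale[0] == pytest.approx(1.0)
        assert out.or_scale[1] == pytest.approx(0.904837, rel=1e-5)
        assert out.or_scale[2] == pytest.approx(1.105171, rel=1e-5)
        assert np.exp(-0.0834) == pytest.approx(0.92, abs=5e-4)

    def test_quantitative_outcome_is_noop_with_warning(self):
        from mrforge.estimators import MREstimate
        est = MREstimate("ivw_fixed", 0.1, 0.05, 0.0, 0.2, 0.04, 10)
        out = to_odds_scale(est, "quantitative")
        assert out.or_scale is None
        assert "warning" in out.extra

    def test_monotone_order_preserved(self):
        from mrforge.estimators import MREstimate
        est = MREstimate("ivw_fixed", -0.05, 0.03, -0.11, 0.01, 0.1, 5)
        out = to_odds_scale(est, "binary")
        assert out.or_scale[1] < out.or_scale[0] < out.or_scale[2]
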