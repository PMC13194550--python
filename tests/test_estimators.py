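"""Wald ratios, radial IVW, weighted median, RAPS and Cochran's Q."""

import numpy as np
import pytest
from scipy import stats

from mrtaxa import (
    HarmonizedSet,
    InputError,
    InsufficientInstrumentsError,
    RadialIVW,
    RAPSEstimator,
    ScenarioConfig,
    WeightedMedianMR,
    cochran_q,
    ivw,
    raps,
    simulate_study,
    wald_ratios,
    weighted_median,
)
from mrtaxa.estimators import _weighted_median, _weights

from conftest import random_harmonized


def hset(gamma, Gamma, se_g=None, se_G=None):
    gamma = np.asarray(gamma, dtype=float)
    se_g = np.zeros_like(gamma) if se_g is None else se_g
    se_G = np.ones_like(gamma) if se_G is None else se_G
    return HarmonizedSet.from_arrays(gamma, se_g, Gamma, se_G)


class TestWaldRatios:
    def test_ratios_and_first_order_weights_by_definition(self):
        h = hset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20])
        rs = wald_ratios(h, "first_order")
        np.testing.assert_allclose(rs.ratio, 0.5)
        np.testing.assert_allclose(rs.weight, [0.01, 0.04, 0.16])

    def test_second_order_reduces_to_first_when_se_gamma_zero(self, rng):
        g = rng.normal(0.2, 0.05, 8)
        G = rng.normal(0.0, 0.1, 8)
        se_G = rng.uniform(0.01, 0.05, 8)
        h = hset(g, G, se_g=np.zeros(8), se_G=se_G)
        np.testing.assert_allclose(wald_ratios(h, "second_order").weight,
                                   wald_ratios(h, "first_order").weight)

    def test_modified_second_order_fixed_point_long_iteration_oracle(self, rng):
        """200 plain iterations from beta=0 reach the same weights."""
        h = random_harmonized(rng, n_snp=10, beta=0.3)
        g, G = h.gamma_hat, h.Gamma_hat
        sg, sG = h.se_gamma, h.se_Gamma
        beta = 0.0
        for _ in range(200):
            w = 1.0 / (sG**2 / g**2 + (beta * g) ** 2 * sg**2 / g**4)
            beta = np.sum(w * (G / g)) / np.sum(w)
        w_oracle = 1.0 / (sG**2 / g**2 + (beta * g) ** 2 * sg**2 / g**4)
        np.testing.assert_allclose(wald_ratios(h, "modified_second_order").weight,
                                   w_oracle, rtol=1e-7)

    def test_zero_gamma_rows_dropped_with_warning(self):
        h = hset([0.0, 0.2], [0.1, 0.1])
        with pytest.warns(UserWarning, match="zero exposure effect"):
            rs = wald_ratios(h)
        assert len(rs.ratio) == 1

    def test_all_zero_gamma_is_degenerate(self):
        with pytest.raises(InputError, match="all exposure effects are zero"):
            wald_ratios(hset([0.0, 0.0], [0.1, 0.1]))


class TestIVW:
    def test_zero_heterogeneity(self):
        h = hset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20])
        e = ivw(h)
        assert e.beta == pytest.approx(0.5)
        assert e.q_stat == pytest.approx(0.0, abs=1e-25)
        assert e.q_pval == pytest.approx(1.0)
        assert e.q_df == e.n_snp - 1

    def test_symmetric_average_closed_form(self):
        # equal weights need equal gamma and equal se_Gamma
        h = hset([0.1, 0.1], [0.02, 0.06], se_G=np.array([0.05, 0.05]))
        e = ivw(h, model="fixed")
        w = 0.1**2 / 0.05**2
        assert e.beta == pytest.approx(0.4)
        assert e.q_stat == pytest.approx(w * (0.04 + 0.04))

    def test_matches_origin_wls_oracle(self, rng):
        """First-order IVW == WLS of Gamma on gamma through the origin."""
        import statsmodels.api as sm

        h = random_harmonized(rng, n_snp=15)
        fit = sm.WLS(h.Gamma_hat, h.gamma_hat, weights=1.0 / h.se_Gamma**2).fit()
        e_fixed = ivw(h, model="fixed")
        e_mre = ivw(h, model="multiplicative_random")
        assert e_fixed.beta == pytest.approx(fit.params[0], rel=1e-12)
        # fixed SE assumes unit scale; WLS bse scales by sqrt(Q/df)
        scale = np.sqrt(e_fixed.q_stat / e_fixed.q_df)
        assert e_fixed.se * scale == pytest.approx(fit.bse[0], rel=1e-10)
        if scale > 1:
            assert e_mre.se == pytest.approx(fit.bse[0], rel=1e-10)

    def test_radial_identity_all_weightings(self, rng):
        """Origin regression of ratio*sqrt(w) on sqrt(w) == weighted mean."""
        for weighting in ("first_order", "second_order", "modified_second_order"):
            h = random_harmonized(rng, n_snp=12)
            rs = wald_ratios(h, weighting)
            x = np.sqrt(rs.weight)
            y = rs.ratio * x
            slope = float(x @ y / (x @ x))
            e = ivw(h, weighting=weighting, model="fixed")
            assert e.beta == pytest.approx(slope, abs=1e-10)

    def test_single_instrument_fallback(self):
        h = hset([0.1], [0.05], se_G=np.array([0.02]))
        e = ivw(h)
        assert e.method == "ivw_fe"
        assert e.n_snp == 1
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.02 / 0.1)  # first-order Wald SE
        assert "single instrument" in e.warnings[0]

    def test_pval_is_two_sided_normal(self, rng):
        h = random_harmonized(rng)
        e = ivw(h)
        assert e.pval == pytest.approx(2 * stats.norm.sf(abs(e.beta) / e.se))


class TestWeightedMedian:
    def test_five_equal_weight_ratios(self):
        h = hset([0.1] * 5, [0.1 * r for r in (1, 2, 3, 4, 5)])
        e = weighted_median(h, n_boot=100, seed=0)
        assert e.beta == pytest.approx(3.0)

    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_equal_weights_reduce_to_sample_median(self, rng, n):
        ratios = rng.normal(0, 1, n)
        h = hset([0.1] * n, 0.1 * ratios)
        e = weighted_median(h, n_boot=100, seed=0)
        assert e.beta == pytest.approx(np.median(ratios))

    def test_grid_scan_oracle(self, rng):
        """Dense-grid inversion of the cumulative-weight curve agrees to 1e-3."""
        for _ in range(10):
            h = random_harmonized(rng, n_snp=9)
            w = h.gamma_hat**2 / h.se_Gamma**2
            r = h.Gamma_hat / h.gamma_hat
            order = np.argsort(r)
            r_s, w_s = r[order], w[order] / w.sum()
            s = np.cumsum(w_s) - w_s / 2
            grid = np.arange(r_s[0], r_s[-1] + 1e-4, 1e-4)
            crossing = grid[np.argmin(np.abs(np.interp(grid, r_s, s) - 0.5))]
            assert _weighted_median(r, w) == pytest.approx(crossing, abs=1e-3)

    def test_bootstrap_se_deterministic_under_seed(self, rng):
        h = random_harmonized(rng)
        e1 = weighted_median(h, n_boot=500, seed=42)
        e2 = weighted_median(h, n_boot=500, seed=42)
        assert e1.se == e2.se

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(hset([0.1, 0.1], [0.05, 0.05]), n_boot=10, seed=0)


class TestRAPS:
    def test_l2_no_overdispersion_equals_ivw_when_se_gamma_zero(self, rng):
        h = random_harmonized(rng, n_snp=12)
        h0 = hset(h.gamma_hat, h.Gamma_hat, se_g=np.zeros(12), se_G=h.se_Gamma)
        e = raps(h0, overdispersion=False, loss="l2")
        assert e.beta == pytest.approx(ivw(h0, model="fixed").beta, abs=1e-6)
        assert e.tau2 == 0.0

    def test_tau2_zero_under_no_pleiotropy(self):
        """Overdispersion estimate clamps at 0 for clean simulated data."""
        tau2 = []
        for rep in range(200):
            exp, out, _ = simulate_study(
                ScenarioConfig(n_snp=15, beta_true=-0.3, seed=50_000 + rep,
                               swap_fraction=0.0, palindromic_fraction=0.0))
            h = HarmonizedSet.from_arrays(
                exp.records["beta"], exp.records["se"],
                out.records["beta"], out.records["se"])
            tau2.append(raps(h, overdispersion=True, loss="l2").tau2)
        assert np.median(tau2) == 0.0

    def test_huber_beats_l2_under_gross_outlier(self, rng):
        """One corrupted ratio among 19: huber stays closer to the clean IVW."""
        wins = 0
        n_rep = 200
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            h = random_harmonized(r, n_snp=19, beta=0.25)
            clean = ivw(h, model="fixed").beta
            G = h.Gamma_hat.copy()
            G[0] += 1.0  # gross pleiotropic offset
            hc = hset(h.gamma_hat, G, se_g=h.se_gamma, se_G=h.se_Gamma)
            b_hub = raps(hc, overdispersion=False, loss="huber").beta
            b_l2 = raps(hc, overdispersion=False, loss="l2").beta
            wins += abs(b_hub - clean) < abs(b_l2 - clean)
        assert wins / n_rep >= 0.95

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            raps(hset([0.1, 0.1], [0.05, 0.05]))

    def test_huber_c_psi_quadrature(self):
        # closed form: E[psi(Z)Z] = P(|Z|<k)·E[Z²| |Z|<k]·... check vs 2(Phi(k)-.5) - 2k phi(k) + 2k² Phi(-k) ... use direct MC
        from mrtaxa.estimators import _huber_c_psi
        z = np.random.default_rng(0).normal(size=2_000_000)
        k = 1.345
        mc = np.mean(np.clip(z, -k, k) * z)
        assert _huber_c_psi(k) == pytest.approx(mc, abs=2e-3)


class TestCochranQ:
    def test_all_ratios_equal(self):
        q, df, p, contrib = cochran_q(hset([0.1, 0.2], [0.05, 0.10]))
        assert q == pytest.approx(0.0, abs=1e-25)
        assert p == pytest.approx(1.0)

    def test_two_equal_weight_ratios_closed_form(self):
        d = 0.4
        h = hset([0.1, 0.1], [0.02, 0.02 + 0.1 * d], se_G=np.array([0.05, 0.05]))
        q, df, p, _ = cochran_q(h)
        w = 0.1**2 / 0.05**2
        assert q == pytest.approx(w * d**2 / 2)
        assert df == 1

    def test_equals_radial_regression_rss(self, rng):
        """Q == residual sum of squares of the unweighted radial fit."""
        for _ in range(5):
            h = random_harmonized(rng, n_snp=10)
            rs = wald_ratios(h, "first_order")
            x = np.sqrt(rs.weight)
            y = rs.ratio * x
            slope, rss = np.linalg.lstsq(x[:, None], y, rcond=None)[0:2]
            q, _, _, contrib = cochran_q(h)
            assert q == pytest.approx(float(rss[0]), rel=1e-10)
            assert contrib.sum() == pytest.approx(q)

    def test_requires_two_variants(self):
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q(hset([0.1], [0.05]))


class TestEquivariance:
    # the weighted-median SE is a parametric-bootstrap quantity, so sign/scale
    # invariance of its SE holds only up to Monte-Carlo error
    FITS = [
        (lambda h: ivw(h), 1e-6),
        (lambda h: weighted_median(h, n_boot=2000, seed=3), 0.15),
        (lambda h: raps(h), 1e-6),
    ]

    @pytest.mark.parametrize("fit,se_rel", FITS, ids=["ivw", "weighted_median", "raps"])
    def test_sign_equivariance(self, rng, fit, se_rel):
        h = random_harmonized(rng, n_snp=11, beta=0.3)
        neg = hset(h.gamma_hat, -h.Gamma_hat, se_g=h.se_gamma, se_G=h.se_Gamma)
        e, en = fit(h), fit(neg)
        assert en.beta == pytest.approx(-e.beta, rel=1e-8)
        assert en.se == pytest.approx(e.se, rel=se_rel)

    @pytest.mark.parametrize("fit,se_rel", FITS, ids=["ivw", "weighted_median", "raps"])
    def test_scale_equivariance(self, rng, fit, se_rel):
        c = 2.5
        h = random_harmonized(rng, n_snp=11, beta=0.3)
        hs = hset(c * h.gamma_hat, h.Gamma_hat, se_g=c * h.se_gamma, se_G=h.se_Gamma)
        e, es = fit(h), fit(hs)
        assert es.beta == pytest.approx(e.beta / c, rel=1e-8)
        assert es.se == pytest.approx(e.se / c, rel=se_rel)

    def test_sklearn_protocol(self, rng):
        est = RadialIVW(weighting="second_order")
        assert est.get_params()["weighting"] == "second_order"
        est.set_params(weighting="first_order")
        h = random_harmonized(rng)
        est.fit(h.gamma_hat, h.Gamma_hat, X_se=h.se_gamma, y_se=h.se_Gamma)
        np.testing.assert_allclose(est.predict([1.0]), [est.beta_])
        assert RAPSEstimator().get_params()["huber_k"] == 1.345
        assert WeightedMedianMR(n_boot=7).get_params()["n_boot"] == 7
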