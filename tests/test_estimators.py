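"""The eight estimators: likelihoods, penalty, scores, spacings, fits."""

import numpy as np
import pytest
from scipy import special

from ggfit import GGParams, LifetimeSample, gg_cdf, gg_logpdf, gg_mean_var, gg_rng
from ggfit import estimators as est
from ggfit.estimators import (
    SCORE_TOL,
    delta_j,
    fit,
    loglik,
    ml_score,
    penalized_loglik,
    penalty_log,
    pml_score,
    spacings,
)


def _fd_grad(fun, theta, eps=1e-6):
    g = np.empty(3)
    for i in range(3):
        d = np.zeros(3)
        d[i] = eps * theta[i]
        g[i] = (fun(theta + d) - fun(theta - d)) / (2 * d[i])
    return g


class TestLoglik:
    def test_equals_sum_of_logpdf(self, sample_a200, theta_b):
        direct = float(np.sum(gg_logpdf(sample_a200.values, theta_b)))
        assert loglik(sample_a200, theta_b) == pytest.approx(direct, abs=1e-10)

    def test_single_exponential_observation(self):
        s = LifetimeSample([1.0])
        assert loglik(s, GGParams(1, 1, 1)) == pytest.approx(-1.0, abs=1e-14)

    def test_score_matches_finite_differences(self, sample_a200):
        theta = np.array([0.7, 0.9, 2.0])
        ana = ml_score(sample_a200, GGParams.from_array(theta))
        num = _fd_grad(lambda a: loglik(sample_a200, GGParams.from_array(a)), theta)
        assert np.allclose(ana, num, rtol=1e-6)


class TestPenalty:
    def test_radicand_positive_on_wide_log_grid(self):
        # the radicand equals mu^2 det(Fisher), so positivity holds wherever
        # the information is positive definite; check the working range
        for phi in np.geomspace(1e-3, 1e3, 61):
            p1 = special.polygamma(1, phi)
            assert phi * phi * p1 * p1 - p1 - 1.0 > 0.0
            assert np.isfinite(penalty_log(GGParams(phi, 1.0, 1.0)))

    def test_algebraic_inversion(self):
        p = GGParams(0.37, 2.2, 1.4)
        p1 = special.polygamma(1, p.phi)
        radicand = p.phi**2 * p1**2 - p1 - 1.0
        back = np.exp(2 * (penalty_log(p) + np.log(p.mu) + np.log(p.alpha)))
        assert back == pytest.approx(radicand, rel=1e-12)

    def test_decreasing_in_mu_and_alpha(self):
        base = penalty_log(GGParams(0.5, 1.0, 1.0))
        assert penalty_log(GGParams(0.5, 2.0, 1.0)) < base
        assert penalty_log(GGParams(0.5, 1.0, 2.0)) < base

    def test_penalized_is_loglik_plus_penalty(self, sample_a20, theta_a):
        assert penalized_loglik(sample_a20, theta_a) == pytest.approx(
            loglik(sample_a20, theta_a) + penalty_log(theta_a), abs=1e-12
        )

    def test_penalty_vanishes_per_observation(self, theta_a):
        # (lP - l)/n -> 0 on nested samples
        gaps = []
        for n in (50, 500, 5000):
            s = gg_rng(n, theta_a, seed=13)
            gaps.append(
                abs(penalized_loglik(s, theta_a) - loglik(s, theta_a)) / n
            )
        assert gaps[0] > gaps[1] > gaps[2]

    def test_pml_score_matches_finite_differences(self, sample_a20):
        theta = np.array([0.6, 0.8, 2.5])
        ana = pml_score(sample_a20, GGParams.from_array(theta))
        num = _fd_grad(
            lambda a: penalized_loglik(sample_a20, GGParams.from_array(a)), theta
        )
        assert np.allclose(ana, num, rtol=1e-6)


class TestDeltaJ:
    def test_closed_form_delta2(self):
        p = GGParams(0.8, 1.2, 2.0)
        t = np.array([0.3, 1.0, 2.5])
        x = (p.mu * t) ** p.alpha
        expect = p.alpha * (p.mu * t) ** (p.phi * p.alpha) * np.exp(-x) / (
            p.mu * special.gamma(p.phi)
        )
        assert np.allclose(delta_j(t, p, 2), expect, rtol=1e-12)

    def test_delta3_sign_follows_log_mu_t(self):
        p = GGParams(0.8, 1.2, 2.0)
        t = np.array([0.5, 1.0 / 1.2, 2.0])
        signs = np.sign(delta_j(t, p, 3))
        assert np.array_equal(signs, np.sign(np.log(p.mu * t)))

    def test_delta1_matches_richardson_oracle(self):
        # higher-order Richardson ladder on the cdf as the reference
        p = GGParams(0.8, 1.2, 2.0)
        t = np.array([0.3, 1.0, 2.5])

        def d_at(h):
            up = gg_cdf(t, GGParams(p.phi + h, p.mu, p.alpha))
            dn = gg_cdf(t, GGParams(p.phi - h, p.mu, p.alpha))
            return (up - dn) / (2 * h)

        d1, d2 = d_at(1e-3), d_at(5e-4)
        oracle = (4 * d2 - d1) / 3
        assert np.allclose(delta_j(t, p, 1), oracle, atol=1e-8)


class TestSpacings:
    def test_sum_to_one_without_ties(self, sample_a20, theta_a):
        sp = spacings(sample_a20, theta_a)
        assert not sp.tie_flags.any()
        assert sp.d.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(sp.d >= 0)

    def test_tie_substitution_keeps_objective_finite(self, theta_a):
        v = gg_rng(30, theta_a, seed=5).values
        v[3] = v[17]  # manufacture one tie
        s = LifetimeSample(v)
        sp = spacings(s, theta_a)
        assert sp.tie_flags.sum() == 1
        assert np.prod(sp.d) == 0.0  # the naive spacings product collapses
        assert np.isfinite(est.mps_objective(s, theta_a))


class TestProfileStructure:
    def test_profile_phi_denominator_positive(self, rng):
        # Chebyshev sum inequality: n sum t^a log t^a > sum t^a sum log t^a
        # whenever two observations differ, so the profile phi stays positive
        for _ in range(1000):
            t = rng.gamma(1.0, 2.0, size=10) + 1e-6
            alpha = rng.uniform(0.2, 5.0)
            w = t**alpha
            lhs = 10 * np.sum(w * np.log(w))
            rhs = np.sum(w) * np.sum(np.log(w))
            assert lhs > rhs

    def test_profile_root_is_full_stationary_point(self, sample_a200):
        r = fit(sample_a200, method="ML", seed=3)
        assert not r.failed
        assert np.max(np.abs(ml_score(sample_a200, r.params))) <= SCORE_TOL


class TestFits:
    def test_pml_default_and_small_sample(self, sample_a20, light_sann):
        r = fit(sample_a20, seed=1, sann_config=light_sann)  # PML is default
        assert r.method == "PML"
        assert not r.failed
        assert np.max(np.abs(pml_score(sample_a20, r.params))) <= SCORE_TOL

    def test_pml_matches_ml_asymptotically(self, theta_a, light_sann):
        s = gg_rng(10_000, theta_a, seed=101)
        rp = fit(s, method="PML", seed=1, sann_config=light_sann)
        rm = fit(s, method="ML", seed=2, sann_config=light_sann)
        assert not rp.failed and not rm.failed
        rel = np.abs(rp.params.as_array() / rm.params.as_array() - 1.0)
        assert np.max(rel) <= 1e-2

    def test_ml_recovery_at_n300(self, theta_a):
        # consistency: mean estimate within 3 Monte-Carlo SEs of the truth
        ests = []
        for k in range(200):
            rng = np.random.default_rng(np.random.SeedSequence((41, k)))
            s = gg_rng(300, theta_a, seed=rng)
            r = est.fit_ml(s, rng=rng, mode="rootfind")
            if not r.failed:
                ests.append(r.params.as_array())
        ests = np.asarray(ests)
        assert ests.shape[0] >= 190
        se = ests.std(axis=0) / np.sqrt(ests.shape[0])
        assert np.all(np.abs(ests.mean(axis=0) - theta_a.as_array()) < 3 * se + 1e-3)

    def test_ml_functional_invariance_on_exponential(self, light_sann):
        s = gg_rng(1000, GGParams(1.0, 1.3, 1.0), seed=6)
        r = fit(s, method="ML", seed=7, sann_config=light_sann)
        assert not r.failed
        fitted_mean, _ = gg_mean_var(r.params)
        assert fitted_mean == pytest.approx(s.values.mean(), rel=0.05)

    def test_mm_success_has_tiny_residuals(self, theta_a):
        s = gg_rng(500, theta_a, seed=21)
        r = est.fit_mm(s, x0=np.array([0.5, 3.0]))
        assert not r.failed
        assert r.score_norm <= 1e-8

    def test_mm_exponential_recovers_rate(self):
        s = gg_rng(2000, GGParams(1.0, 1.0, 1.0), seed=8)
        r = est.fit_mm(s, x0=np.array([1.0, 1.0]))
        assert not r.failed
        # with shape estimates near one the scale must sit near 1/mean
        assert r.params.mu == pytest.approx(1.0 / s.values.mean(), rel=0.25)

    def test_ols_wls_optimum_beats_random_probes(self, sample_a20, rng, theta_a):
        for fitter, obj in ((est.fit_ols, est.ols_objective),
                            (est.fit_wls, est.wls_objective)):
            r = fitter(sample_a20, x0=theta_a.as_array())
            assert not r.failed
            assert r.score_norm <= 1e-6  # the stationarity equations
            probes = rng.uniform(0.05, 4.0, size=(100, 3))
            vals = [obj(sample_a20, GGParams.from_array(p)) for p in probes]
            assert r.objective <= min(vals)

    def test_wls_first_weight(self):
        n = 19
        assert est._wls_weights(n)[0] == pytest.approx((n + 1) ** 2 * (n + 2) / n)

    def test_mps_handles_duplicate_value(self, theta_a, light_sann):
        v = gg_rng(24, theta_a, seed=31).values
        v[5] = v[11]
        s = LifetimeSample(v)
        r = est.fit_mps(s, seed=3, sann_config=light_sann)
        assert not r.failed
        assert np.isfinite(r.objective)

    def test_ad_objective_equals_textbook_statistic(self, theta_a, rng):
        # brute-force A^2 = -n - (1/n) sum (2i-1)[ln u_(i) + ln(1-u_(n+1-i))]
        for _ in range(10):
            s = gg_rng(15, theta_a, seed=int(rng.integers(2**31)))
            p = GGParams(*rng.uniform(0.3, 2.5, 3))
            u = np.sort(gg_cdf(s.sorted, p))
            i = np.arange(1, 16)
            brute = -15 - np.sum((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1]))) / 15
            # the oracle's 1-u loses precision where u ~ 1, so micro-level
            # agreement is all it can certify
            assert est.ad_objective(s, p) == pytest.approx(brute, rel=1e-6)

    def test_ad_minimum_below_value_at_truth(self, theta_a, light_sann):
        s = gg_rng(100, theta_a, seed=17)
        r = est.fit_ad(s, seed=4, sann_config=light_sann)
        assert not r.failed
        assert r.objective <= est.ad_objective(s, theta_a) + 1e-10

    def test_ad_consistency_mean_over_replicates(self, theta_b, light_sann):
        ests = []
        for k in range(8):
            rng = np.random.default_rng(np.random.SeedSequence((88, k)))
            s = gg_rng(3000, theta_b, seed=rng)
            r = est.fit_ad(s, rng=rng, sann_config=light_sann)
            if not r.failed:
                ests.append(r.params.as_array())
        mean = np.mean(ests, axis=0)
        assert np.all(np.abs(mean / theta_b.as_array() - 1.0) < 0.05)

    def test_rad_fit_solves_its_equations(self, sample_a200, light_sann):
        r = est.fit_rad(sample_a200, seed=5, sann_config=light_sann)
        assert not r.failed
        assert np.max(np.abs(est.rad_score(sample_a200, r.params))) <= SCORE_TOL


class TestEquivariance:
    """Shape estimates are scale-free; the rate scales like 1/c under t -> c t."""

    C = 10.0

    @pytest.mark.parametrize("method", ["PML", "ML", "MPS", "AD", "RAD"])
    def test_sann_methods(self, theta_a, light_sann, method):
        # n large enough that an interior optimum exists for every method
        s = gg_rng(120, theta_a, seed=19)
        x0 = np.array([0.6, 0.6, 2.8])
        r1 = fit(s, method=method, seed=3, x0=x0, sann_config=light_sann)
        scaled = LifetimeSample(self.C * s.values)
        r2 = fit(scaled, method=method, seed=3, x0=x0 / [1, self.C, 1],
                 sann_config=light_sann)
        assert not r1.failed and not r2.failed
        a1, a2 = r1.params.as_array(), r2.params.as_array()
        assert a2[0] == pytest.approx(a1[0], rel=1e-3)
        assert a2[1] == pytest.approx(a1[1] / self.C, rel=1e-3)
        assert a2[2] == pytest.approx(a1[2], rel=1e-3)

    @pytest.mark.parametrize("method", ["MM", "OLS", "WLS"])
    def test_rootfind_methods(self, theta_a, method):
        s = gg_rng(120, theta_a, seed=19)
        x0 = theta_a.as_array()
        r1 = fit(s, method=method, x0=x0)
        scaled = LifetimeSample(self.C * s.values)
        r2 = fit(scaled, method=method, x0=x0 / [1, self.C, 1])
        assert not r1.failed and not r2.failed
        a1, a2 = r1.params.as_array(), r2.params.as_array()
        assert a2[0] == pytest.approx(a1[0], rel=1e-3)
        assert a2[1] == pytest.approx(a1[1] / self.C, rel=1e-3)
        assert a2[2] == pytest.approx(a1[2], rel=1e-3)


class TestFailureTaxonomy:
    def test_degenerate_sample(self):
        s = LifetimeSample([2.0, 2.0, 2.0, 2.0, 2.0])
        for method in ("PML", "ML", "MM", "MPS"):
            r = fit(s, method=method, seed=1)
            assert r.failed
            assert "degenerate" in r.failure_reason

    def test_too_small_sample(self):
        s = LifetimeSample([1.0, 2.0, 3.0])
        r = fit(s, method="PML", seed=1)
        assert r.failed and "n=3" in r.failure_reason

    def test_unknown_method_rejected(self, sample_a20):
        with pytest.raises(ValueError):
            fit(sample_a20, method="EM")

    def test_result_serializes(self, sample_a20, light_sann):
        d = fit(sample_a20, seed=1, sann_config=light_sann).to_dict()
        assert set(d["params"]) == {"phi", "mu", "alpha"}
        assert d["failed"] is False
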