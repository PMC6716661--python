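"""The GG distribution itself: densities, moments, sampler, mean residual life."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from ggfit import (
    GGParams,
    LifetimeSample,
    gg_cdf,
    gg_hazard,
    gg_logpdf,
    gg_mean_residual,
    gg_mean_var,
    gg_moment,
    gg_pdf,
    gg_quantile,
    gg_rng,
    gg_survival,
)

TABLE5_PARAMS = {
    "D1": GGParams(0.410, 0.025, 3.040),
    "D2": GGParams(0.268, 0.045, 4.658),
    "D3": GGParams(0.148, 0.053, 6.065),
}


class TestValidation:
    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -2, 1), (1, 1, np.inf), (np.nan, 1, 1)])
    def test_params_must_be_positive_finite(self, bad):
        with pytest.raises(ValueError):
            GGParams(*bad)

    def test_sample_rejects_nonpositive_and_reports_rows(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            LifetimeSample([1.0, -3.0, 2.0])
        with pytest.raises(ValueError):
            LifetimeSample([])

    def test_sample_sorted_is_order_statistics(self, rng):
        v = rng.gamma(2, 1, 50)
        s = LifetimeSample(v)
        assert np.array_equal(s.sorted, np.sort(v))
        assert s.n == 50

    def test_from_csv_with_and_without_header(self, tmp_path):
        p1 = tmp_path / "with_header.csv"
        p1.write_text("days\n1.5\n2\n3\n")
        p2 = tmp_path / "bare.csv"
        p2.write_text("1.5\n2\n3\n")
        for p in (p1, p2):
            s = LifetimeSample.from_csv(p)
            assert np.allclose(np.sort(s.values), [1.5, 2.0, 3.0])

    def test_from_csv_flags_bad_rows(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("days\n2\noops\n3\n")
        with pytest.raises(ValueError):
            LifetimeSample.from_csv(p)


class TestSubmodelReductions:
    """phi=1 collapses to the Weibull, alpha=1 to the Gamma: all four
    functions must agree with the closed sub-model forms to 1e-10."""

    T = np.linspace(0.05, 6.0, 40)

    @pytest.mark.parametrize("mu,alpha", [(1.0, 1.0), (2.0, 0.7), (0.5, 3.0)])
    def test_weibull_reduction(self, mu, alpha):
        p = GGParams(1.0, mu, alpha)
        ref = stats.weibull_min(c=alpha, scale=1.0 / mu)
        assert np.allclose(gg_pdf(self.T, p), ref.pdf(self.T), atol=1e-10, rtol=1e-10)
        assert np.allclose(gg_cdf(self.T, p), ref.cdf(self.T), atol=1e-10)
        assert np.allclose(gg_survival(self.T, p), ref.sf(self.T), atol=1e-10)
        assert np.allclose(
            gg_hazard(self.T, p), ref.pdf(self.T) / ref.sf(self.T), rtol=1e-10
        )

    @pytest.mark.parametrize("phi,mu", [(0.5, 1.0), (2.5, 0.3), (1.7, 4.0)])
    def test_gamma_reduction(self, phi, mu):
        p = GGParams(phi, mu, 1.0)
        ref = stats.gamma(a=phi, scale=1.0 / mu)
        assert np.allclose(gg_pdf(self.T, p), ref.pdf(self.T), atol=1e-10, rtol=1e-10)
        assert np.allclose(gg_cdf(self.T, p), ref.cdf(self.T), atol=1e-10)
        assert np.allclose(gg_survival(self.T, p), ref.sf(self.T), atol=1e-10)

    def test_exponential_point_value(self):
        # phi = mu = alpha = 1 at t = 0.5 is e^{-1/2}
        assert gg_pdf(0.5, GGParams(1, 1, 1)) == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_constant_hazard_of_exponential(self):
        p = GGParams(1.0, 0.8, 1.0)
        h = gg_hazard(np.linspace(0.1, 20, 30), p)
        assert np.allclose(h, 0.8, rtol=1e-10)


class TestDensityIntegrals:
    @pytest.mark.parametrize(
        "phi,alpha",
        [(p, a) for p in (0.1, 0.5, 1.0, 2.0, 5.0) for a in (0.5, 1.0, 3.0, 8.0)],
    )
    def test_pdf_normalizes(self, phi, alpha):
        # split at a small point: the density can have an integrable
        # singularity at zero (alpha*phi < 1) that defeats one-shot quad
        p = GGParams(phi, 0.7, alpha)
        head, _ = integrate.quad(lambda t: gg_pdf(t, p), 0, 1e-6, limit=300)
        tail, _ = integrate.quad(lambda t: gg_pdf(t, p), 1e-6, np.inf, limit=300)
        assert head + tail == pytest.approx(1.0, abs=1e-8)

    def test_cdf_matches_quadrature(self, theta_b):
        grid = np.linspace(0.05, 1.6, 20)
        for t in grid:
            num, _ = integrate.quad(lambda w: gg_pdf(w, theta_b), 0, t, limit=300)
            assert gg_cdf(t, theta_b) == pytest.approx(num, abs=1e-8)

    def test_survival_complements_cdf(self, theta_a):
        t = np.linspace(0.01, 8, 200)
        assert np.allclose(gg_cdf(t, theta_a) + gg_survival(t, theta_a), 1.0, atol=1e-12)
        assert gg_cdf(0.0, theta_a) == 0.0
        assert gg_survival(0.0, theta_a) == 1.0

    def test_cdf_monotone_survival_antitone(self, theta_b):
        t = np.linspace(0.001, 5, 500)
        assert np.all(np.diff(gg_cdf(t, theta_b)) >= 0)
        assert np.all(np.diff(gg_survival(t, theta_b)) <= 0)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    phi=st.floats(0.05, 20.0),
    mu=st.floats(0.05, 20.0),
    alpha=st.floats(0.2, 10.0),
    t=st.floats(1e-3, 50.0),
)
def test_cdf_in_unit_interval_and_consistent(phi, mu, alpha, t):
    p = GGParams(phi, mu, alpha)
    c = gg_cdf(t, p)
    assert 0.0 <= c <= 1.0
    assert c + gg_survival(t, p) == pytest.approx(1.0, abs=1e-10)
    assert gg_pdf(t, p) >= 0.0


class TestHazardShapes:
    def _slope_signs(self, p):
        t = np.linspace(0.2, 6.0, 120)
        return np.sign(np.diff(gg_hazard(t, p)))

    def test_increasing_hazard(self):
        assert np.all(self._slope_signs(GGParams(3.0, 0.5, 1.5)) > 0)

    def test_decreasing_hazard(self):
        assert np.all(self._slope_signs(GGParams(0.5, 1.0, 0.8)) < 0)

    def test_hazard_is_pdf_over_survival(self, theta_a):
        t = np.linspace(0.1, 4, 50)
        ratio = gg_pdf(t, theta_a) / gg_survival(t, theta_a)
        assert np.allclose(gg_hazard(t, theta_a), ratio, rtol=1e-10)

    def test_underflowed_survival_warns(self):
        with pytest.warns(RuntimeWarning):
            h = gg_hazard(1e4, GGParams(1.0, 1.0, 2.0))
        assert np.isinf(h)


class TestMoments:
    def test_zeroth_moment_is_one(self, theta_a):
        assert gg_moment(0.0, theta_a) == pytest.approx(1.0, abs=1e-14)

    def test_exponential_mean(self):
        assert gg_moment(1.0, GGParams(1, 2.5, 1)) == pytest.approx(1 / 2.5, rel=1e-12)

    def test_exponential_mean_var(self):
        m, v = gg_mean_var(GGParams(1.0, 2.0, 1.0))
        assert m == pytest.approx(0.5, rel=1e-12)
        assert v == pytest.approx(0.25, rel=1e-12)

    def test_variance_identity(self, theta_b):
        m, v = gg_mean_var(theta_b)
        assert v == pytest.approx(
            gg_moment(2, theta_b) - gg_moment(1, theta_b) ** 2, abs=1e-12
        )

    def test_monte_carlo_agreement(self, theta_a):
        draws = gg_rng(200_000, theta_a, seed=3).values
        for r in (1.0, 2.0):
            x = draws**r
            se = x.std() / np.sqrt(x.size)
            assert abs(x.mean() - gg_moment(r, theta_a)) < 3 * se


class TestMeanResidualLife:
    def test_at_zero_equals_mean(self, theta_b):
        assert gg_mean_residual(0.0, theta_b) == pytest.approx(
            gg_mean_var(theta_b)[0], rel=1e-12
        )

    def test_hospital_stay_predictions_in_days(self):
        # after ten days in hospital: about 17 further days for the
        # total-stay parameters, about 4 for the ventilation parameters
        assert round(gg_mean_residual(10.0, TABLE5_PARAMS["D1"])) == 17
        assert round(gg_mean_residual(10.0, TABLE5_PARAMS["D3"])) == 4

    @pytest.mark.parametrize("name", ["D1", "D2", "D3"])
    def test_matches_survival_quadrature(self, name):
        # r(t) = int_t^inf S(w) dw / S(t)
        p = TABLE5_PARAMS[name]
        t0 = 10.0
        num, _ = integrate.quad(lambda w: gg_survival(w, p), t0, 500.0, limit=400)
        assert gg_mean_residual(t0, p) == pytest.approx(
            num / gg_survival(t0, p), abs=1e-6
        )

    def test_beyond_support_resolution_raises(self):
        with pytest.raises(ValueError):
            gg_mean_residual(1e6, GGParams(1.0, 1.0, 2.0))


class TestQuantile:
    def test_roundtrip(self, theta_a):
        q = np.array([0.01, 0.25, 0.5, 0.9, 0.999])
        t = gg_quantile(q, theta_a)
        assert np.allclose(gg_cdf(t, theta_a), q, atol=1e-9)

    def test_edges(self, theta_a):
        assert gg_quantile(0.0, theta_a) == 0.0
        assert np.isinf(gg_quantile(1.0, theta_a))


class TestSampler:
    def test_seed_reproducibility(self, theta_a):
        a = gg_rng(100, theta_a, seed=11).values
        b = gg_rng(100, theta_a, seed=11).values
        assert np.array_equal(a, b)

    def test_power_transform_is_gamma(self, theta_a):
        # (mu T)^alpha must be Gamma(phi, 1)
        t = gg_rng(100_000, theta_a, seed=5).values
        w = (theta_a.mu * t) ** theta_a.alpha
        p = stats.kstest(w, stats.gamma(a=theta_a.phi).cdf).pvalue
        assert p > 0.01

    def test_empirical_cdf_within_dkw_band(self, theta_b):
        n = 100_000
        t = np.sort(gg_rng(n, theta_b, seed=9).values)
        ecdf = np.arange(1, n + 1) / n
        eps = np.sqrt(np.log(2 / 0.001) / (2 * n))  # 99.9% DKW band
        assert np.max(np.abs(ecdf - gg_cdf(t, theta_b))) < eps
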