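"""Hierarchical model: design, priors, kernels, fitting and recovery."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import integrate, stats

from cyclemetry.config import ModelConfig, WEEKS_PER_YEAR
from cyclemetry.model import (PosteriorDraws, _student_t_logpdf, build_design,
                              fit_model, gp_covariance, hpd_interval,
                              posterior_expectation_curve, skew_normal_logpdf)
from cyclemetry.strata import DRSeries


def _make_series(dr, start=0, sid=0, age_group=1):
    n = len(dr)
    return DRSeries(stratum_id=sid, weeks=np.arange(start, start + n),
                    enrollees=np.full(n, 1000), diagnoses=np.zeros(n),
                    dr=np.asarray(dr, float), sex="F", age_group=age_group)


class TestDesign:
    def test_shift_columns_zero_before_first_boundary(self):
        cfg = ModelConfig(n_harmonics=1, year_boundaries=(52, 104))
        X = build_design([10, 20, 50], cfg)
        np.testing.assert_array_equal(X[:, 2:4], 0)

    def test_quarter_period_harmonic_columns(self):
        cfg = ModelConfig(n_harmonics=1, year_boundaries=())
        X = build_design([WEEKS_PER_YEAR / 4], cfg)
        assert X[0, 2] == pytest.approx(0.0, abs=1e-12)   # cos
        assert X[0, 3] == pytest.approx(1.0, abs=1e-12)   # sin

    def test_cumulative_indicators(self):
        cfg = ModelConfig(n_harmonics=0, year_boundaries=(52, 104, 156))
        X = build_design([105], cfg)
        np.testing.assert_array_equal(X[0, 2:5], [1.0, 1.0, 0.0])

    def test_column_count(self):
        cfg = ModelConfig(n_harmonics=3, year_boundaries=(52,))
        assert build_design(np.arange(5), cfg).shape == (5, 2 + 1 + 6)


class TestSkewNormal:
    def test_zero_shape_is_normal(self, rng):
        x = rng.normal(size=200) * 5
        ours = skew_normal_logpdf(x, loc=1.2, scale=2.5, shape=0.0)
        ref = stats.norm.logpdf(x, loc=1.2, scale=2.5)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_at_location(self):
        for h in (-3, 0, 2):
            assert skew_normal_logpdf(0.0, 0.0, 1.0, h) == pytest.approx(
                math.log(stats.norm.pdf(0)), abs=1e-12)

    def test_against_scipy_skewnorm(self, rng):
        x = rng.normal(size=100) * 4
        for mu, sig, h in [(0, 1, 5), (2, 3, -4), (-1, 0.5, 1.5)]:
            ours = skew_normal_logpdf(x, mu, sig, h)
            ref = stats.skewnorm.logpdf(x, h, loc=mu, scale=sig)
            np.testing.assert_allclose(ours, ref, atol=1e-10)

    @pytest.mark.parametrize("mu,sig,h", [(0, 1, 5), (2, 3, -4)])
    def test_normalization_by_quadrature(self, mu, sig, h):
        val, _ = integrate.quad(
            lambda x: math.exp(skew_normal_logpdf(x, mu, sig, h)),
            mu - 30 * sig, mu + 30 * sig, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            skew_normal_logpdf(0.0, 0.0, -1.0, 0.0)

    def test_symmetric_at_zero_shape_own_sampler(self, rng):
        # skew-normal representation: delta |Z0| + sqrt(1-delta^2) Z1;
        # h = 0 -> delta = 0 -> symmetric draws
        h = 0.0
        delta = h / math.sqrt(1 + h * h)
        z0, z1 = rng.standard_normal((2, 100_000))
        draws = delta * np.abs(z0) + math.sqrt(1 - delta ** 2) * z1
        assert abs(stats.skew(draws)) < 0.1
        # and a strong positive shape is right-skewed
        h = 5.0
        delta = h / math.sqrt(1 + h * h)
        skewed = delta * np.abs(z0) + math.sqrt(1 - delta ** 2) * z1
        assert stats.skew(skewed) > 0.5


class TestGPKernel:
    def test_diagonal_is_scale_squared(self):
        K = gp_covariance(np.arange(6), scale=2.0, length=1.5)
        np.testing.assert_allclose(np.diag(K), 4.0)

    def test_long_length_limit_shares_everything(self):
        K = gp_covariance(np.arange(4), scale=1.3, length=1e8)
        np.testing.assert_allclose(K, 1.3 ** 2, rtol=1e-10)

    def test_positive_semidefinite(self):
        K = gp_covariance(np.arange(6), scale=1.0, length=1.0)
        assert np.linalg.eigvalsh(K).min() >= -1e-10
        np.testing.assert_allclose(K, K.T)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            gp_covariance(np.arange(3), scale=-1.0, length=1.0)
        with pytest.raises(ValueError):
            gp_covariance(np.arange(3), scale=1.0, length=0.0)


class TestStudentT:
    def test_matches_scipy(self, rng):
        x = rng.normal(size=50)
        for nu, mu, sig in [(3, 0, 1), (7.5, 0.2, 0.05), (30, -1, 2)]:
            ours = _student_t_logpdf(x, mu, sig, nu)
            ref = stats.t.logpdf(x, df=nu, loc=mu, scale=sig)
            np.testing.assert_allclose(ours, ref, atol=1e-10)


class TestHPD:
    def test_normal_interval(self, rng):
        x = rng.standard_normal(200_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)


@pytest.fixture(scope="module")
def noiseless_fit():
    t = np.arange(150)
    alpha, beta, A, phi = 0.01, 2e-5, 0.002, 0.6
    dr = alpha + beta * t + A * np.sin(2 * np.pi * t / WEEKS_PER_YEAR + phi)
    cfg = ModelConfig(n_harmonics=1, year_boundaries=(),
                      n_burn=300, n_draws=200, seed=5)
    draws = fit_model([_make_series(dr)], cfg)
    return draws, dict(alpha=alpha, beta=beta, A=A, phi=phi, t=t, dr=dr)


class TestFit:
    def test_noiseless_recovery_within_5pct(self, noiseless_fit):
        draws, truth = noiseless_fit
        assert draws.alpha.mean() == pytest.approx(truth["alpha"], rel=0.05)
        assert draws.beta.mean() == pytest.approx(truth["beta"], rel=0.05)

    def test_posterior_mean_curve_tracks_truth(self, noiseless_fit):
        draws, truth = noiseless_fit
        mean, lo, hi = posterior_expectation_curve(draws, 0, truth["t"])
        ss_res = np.sum((mean - truth["dr"]) ** 2)
        ss_tot = np.sum((truth["dr"] - truth["dr"].mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.9
        assert (lo <= hi).all()
        # the noiseless truth lies inside the band nearly everywhere
        inside = (lo <= truth["dr"]) & (truth["dr"] <= hi)
        assert inside.mean() > 0.8

    def test_curve_is_linear_functional_of_draws(self, noiseless_fit):
        draws, truth = noiseless_fit
        mean, _, _ = posterior_expectation_curve(draws, 0, truth["t"])
        X = build_design(truth["t"], draws.config)
        coef = np.concatenate([
            [draws.alpha[:, 0].mean(), draws.beta[:, 0].mean()],
            [draws.p[:, 0, 0].mean(), draws.q[:, 0, 0].mean()]])
        np.testing.assert_allclose(mean, X @ coef, rtol=1e-10)

    def test_deterministic_under_seed(self):
        t = np.arange(110)
        rng = np.random.default_rng(2)
        dr = 0.01 + 0.002 * np.sin(2 * np.pi * t / WEEKS_PER_YEAR) \
            + 0.0005 * rng.standard_normal(110)
        cfg = ModelConfig(n_harmonics=1, year_boundaries=(),
                          n_burn=80, n_draws=60, seed=9)
        d1 = fit_model([_make_series(dr)], cfg)
        d2 = fit_model([_make_series(dr)], cfg)
        np.testing.assert_array_equal(d1.alpha, d2.alpha)
        np.testing.assert_array_equal(d1.q, d2.q)

    def test_exchangeable_strata_agree(self):
        t = np.arange(120)
        rng = np.random.default_rng(3)
        dr = 0.01 + 0.002 * np.sin(2 * np.pi * t / WEEKS_PER_YEAR + 0.5) \
            + 0.0008 * rng.standard_normal(120)
        s1 = _make_series(dr, sid=0)
        s2 = _make_series(dr.copy(), sid=1)
        cfg = ModelConfig(n_harmonics=1, year_boundaries=(),
                          n_burn=250, n_draws=200, seed=4)
        draws = fit_model([s1, s2], cfg)
        # identical data -> posterior means agree within Monte-Carlo error
        # (effective sample size is well below the raw draw count, so the
        # tolerance is relative to the posterior location)
        assert draws.alpha[:, 0].mean() == pytest.approx(
            draws.alpha[:, 1].mean(), rel=0.05)
        assert draws.p[:, 0, 0].mean() == pytest.approx(
            draws.p[:, 1, 0].mean(), abs=3e-4)

    def test_shift_shrinkage_when_scale_collapses(self):
        # a real New-Year jump, but a near-zero Laplace scale on the shifts:
        # posterior gamma collapse toward 0 and the trend absorbs the drift
        t = np.arange(160)
        rng = np.random.default_rng(6)
        jump = 0.004
        dr = 0.01 + jump * (t > 80) + 0.0005 * rng.standard_normal(160)
        cfg_free = ModelConfig(n_harmonics=0, year_boundaries=(80,),
                               n_burn=250, n_draws=150, seed=8)
        cfg_tight = dataclasses.replace(cfg_free, shift_scale=1e-5)
        free = fit_model([_make_series(dr)], cfg_free)
        tight = fit_model([_make_series(dr)], cfg_tight)
        assert abs(free.gamma.mean()) > 0.5 * jump        # jump detected
        assert abs(tight.gamma.mean()) < 0.05 * jump      # collapsed
        assert tight.beta.mean() > free.beta.mean()       # slope absorbs it

    def test_boundary_relabeling_equivalence(self):
        # boundaries supplied as equal values through different containers
        # produce identical designs and identical fitted draws
        t = np.arange(120)
        dr = 0.01 + 0.001 * np.sin(2 * np.pi * t / WEEKS_PER_YEAR)
        c1 = ModelConfig(n_harmonics=1, year_boundaries=tuple([52, 104]),
                         n_burn=60, n_draws=40, seed=3)
        c2 = ModelConfig(n_harmonics=1,
                         year_boundaries=tuple(int(x) for x in np.array([52, 104])),
                         n_burn=60, n_draws=40, seed=3)
        np.testing.assert_array_equal(build_design(t, c1), build_design(t, c2))
        d1 = fit_model([_make_series(dr)], c1)
        d2 = fit_model([_make_series(dr)], c2)
        np.testing.assert_array_equal(d1.alpha, d2.alpha)

    def test_insufficient_observations_rejected(self):
        cfg = ModelConfig(n_harmonics=5, year_boundaries=(52, 104))
        with pytest.raises(ValueError, match="observed weeks"):
            fit_model([_make_series(np.full(10, 0.01))], cfg)

    def test_zero_variance_draws_give_zero_band(self, noiseless_fit):
        draws, truth = noiseless_fit
        frozen = PosteriorDraws(
            alpha=np.repeat(draws.alpha[:1], 50, axis=0),
            beta=np.repeat(draws.beta[:1], 50, axis=0),
            gamma=np.repeat(draws.gamma[:1], 50, axis=0),
            p=np.repeat(draws.p[:1], 50, axis=0),
            q=np.repeat(draws.q[:1], 50, axis=0),
            sigma_y=np.repeat(draws.sigma_y[:1], 50, axis=0),
            nu=np.repeat(draws.nu[:1], 50, axis=0),
            hyper=np.repeat(draws.hyper[:1], 50, axis=0),
            gp=np.repeat(draws.gp[:1], 50, axis=0),
            strata_meta=draws.strata_meta, config=draws.config)
        mean, lo, hi = posterior_expectation_curve(frozen, 0, truth["t"])
        np.testing.assert_array_equal(lo, mean)
        np.testing.assert_array_equal(hi, mean)
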