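"""Harmonic pooling, amplitude/phase, s(t) and baseline correction."""

import numpy as np
import pytest

from cyclemetry.config import ModelConfig, WEEKS_PER_YEAR
from cyclemetry.model import PosteriorDraws
from cyclemetry.seasonality import (PooledHarmonics, SeasonalityCurve,
                                    amplitude_phase, annual_grid,
                                    corrected_seasonality, harmonic_curve,
                                    pool_harmonics, prevalence_filter,
                                    time_average_dr, uncorrected_seasonality)
from cyclemetry.strata import DRSeries, SoftStratum


def _draws_for(p_by_stratum, q_by_stratum, n_samples=1, age_group=1):
    S = len(p_by_stratum)
    N = len(p_by_stratum[0])
    p = np.tile(np.asarray(p_by_stratum, float), (n_samples, 1, 1))
    q = np.tile(np.asarray(q_by_stratum, float), (n_samples, 1, 1))
    zeros = np.zeros((n_samples, S))
    meta = [{"stratum_id": i, "sex": "F", "age_group": age_group,
             "weeks": (0, 100)} for i in range(S)]
    return PosteriorDraws(
        alpha=zeros, beta=zeros, gamma=np.zeros((n_samples, S, 0)),
        p=p, q=q, sigma_y=zeros + 1, nu=zeros + 10,
        hyper=np.zeros((n_samples, 1, 6)), gp=np.zeros((n_samples, 4)),
        strata_meta=meta, age_groups=np.full(S, age_group),
        config=ModelConfig(n_harmonics=N, year_boundaries=()))


def _strata(person_weeks, age_group=1):
    return [SoftStratum(stratum_id=i, sex="F", age_group=age_group,
                        window_start=0, window_end=100, total_members=10,
                        total_person_weeks=int(w))
            for i, w in enumerate(person_weeks)]


class TestPooling:
    def test_single_stratum_identity(self):
        d = _draws_for([[0.3, 0.1]], [[0.2, -0.1]])
        pooled = pool_harmonics(d, _strata([100]))
        np.testing.assert_allclose(pooled.p_mean, [0.3, 0.1])
        np.testing.assert_allclose(pooled.q_mean, [0.2, -0.1])
        assert pooled.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_weights_average(self):
        d = _draws_for([[0.1], [0.3]], [[0.0], [0.0]])
        pooled = pool_harmonics(d, _strata([50, 50]))
        assert pooled.p_mean[0] == pytest.approx(0.2, abs=1e-12)

    def test_arbitrary_weights_match_dot_product(self, rng):
        S, N = 5, 3
        p = rng.normal(size=(S, N))
        q = rng.normal(size=(S, N))
        pw = rng.integers(1, 1000, size=S)
        d = _draws_for(p, q)
        pooled = pool_harmonics(d, _strata(pw))
        w = pw / pw.sum()
        np.testing.assert_allclose(pooled.p_mean, w @ p, atol=1e-12)
        np.testing.assert_allclose(pooled.q_mean, w @ q, atol=1e-12)

    def test_age_group_filter(self):
        d = _draws_for([[0.1], [0.5]], [[0.0], [0.0]])
        strata = (_strata([10], age_group=1)
                  + [SoftStratum(stratum_id=1, sex="F", age_group=2,
                                 window_start=0, window_end=100,
                                 total_members=10, total_person_weeks=10)])
        d.strata_meta[1]["age_group"] = 2
        pooled = pool_harmonics(d, strata, age_group=1)
        assert pooled.p_mean[0] == pytest.approx(0.1)

    def test_zero_weight_rejected(self):
        d = _draws_for([[0.1]], [[0.0]])
        with pytest.raises(ValueError, match="weight"):
            pool_harmonics(d, _strata([0]))

    def test_pooling_commutes_with_reparametrization(self, rng):
        # pooling then A,phi equals A,phi of the pooled bases
        S = 4
        p = rng.normal(size=(S, 2))
        q = rng.normal(size=(S, 2))
        pw = rng.integers(1, 100, size=S)
        d = _draws_for(p, q)
        pooled = pool_harmonics(d, _strata(pw))
        A1, phi1 = amplitude_phase(pooled.p_mean, pooled.q_mean)
        w = pw / pw.sum()
        A2, phi2 = amplitude_phase(w @ p, w @ q)
        np.testing.assert_allclose(A1, A2, atol=1e-12)
        np.testing.assert_allclose(phi1, phi2, atol=1e-12)


class TestAmplitudePhase:
    def test_three_four_five(self):
        A, phi = amplitude_phase(3.0, 4.0)
        assert A == pytest.approx(5.0)
        assert phi == pytest.approx(np.arctan2(3, 4), abs=1e-12)

    def test_pure_sine(self):
        A, phi = amplitude_phase(0.0, 1.0)
        assert A == 1.0 and phi == 0.0

    def test_zero_amplitude_phase_convention(self):
        A, phi = amplitude_phase(0.0, 0.0)
        assert A == 0.0 and phi == 0.0

    def test_reconstruction_on_fine_grid(self, rng):
        # p cos + q sin == A sin(. + phi) pointwise at 0.01-week resolution
        t = np.arange(0, WEEKS_PER_YEAR, 0.01)
        ang = 2 * np.pi * t / WEEKS_PER_YEAR
        for _ in range(100):
            p, q = rng.normal(size=2)
            A, phi = amplitude_phase(p, q)
            direct = p * np.cos(ang) + q * np.sin(ang)
            repar = A * np.sin(ang + phi)
            assert np.max(np.abs(direct - repar)) < 1e-10


class TestTimeAverageDR:
    def _series(self, dr):
        n = len(dr)
        return DRSeries(stratum_id=0, weeks=np.arange(n),
                        enrollees=np.full(n, 100),
                        diagnoses=np.asarray(dr) * 100, dr=np.asarray(dr, float),
                        sex="F", age_group=1)

    def test_constant(self):
        assert time_average_dr([self._series([0.01] * 10)]) == pytest.approx(0.01)

    def test_two_week_mean(self):
        assert time_average_dr([self._series([0.02, 0.04])]) == pytest.approx(0.03)

    def test_hand_enumerated_panel(self, hand_panel):
        from cyclemetry.strata import (build_hard_strata, compute_dr_series,
                                       merge_strata_kmeans)
        members, claims = hand_panel
        soft = merge_strata_kmeans(build_hard_strata(members), 1, seed=0)
        ser = compute_dr_series(soft[0], members, claims, "X")
        # manual: (0+0+2/3+0+0+1+0+0+0+0)/10
        assert time_average_dr([ser]) == pytest.approx((2 / 3 + 1) / 10)

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError):
            time_average_dr([self._series([0.01] * 10)], span=(50, 60))


class TestSeasonalityCurves:
    def test_zero_harmonics_zero_curve(self):
        pooled = PooledHarmonics(p_draws=np.zeros((5, 2)),
                                 q_draws=np.zeros((5, 2)),
                                 weights=np.array([1.0]))
        curve = uncorrected_seasonality(pooled, 0.1)
        np.testing.assert_array_equal(curve.s, 0)

    def test_single_harmonic_closed_form(self):
        # q1 = 0.01, <DR> = 0.1 -> peak 10% at t = W/4
        pooled = PooledHarmonics(p_draws=np.zeros((3, 1)),
                                 q_draws=np.full((3, 1), 0.01),
                                 weights=np.array([1.0]))
        t = np.array([0.0, WEEKS_PER_YEAR / 4])
        curve = uncorrected_seasonality(pooled, 0.1, t=t)
        assert curve.s[1] == pytest.approx(0.10, abs=1e-12)
        assert abs(curve.s[0]) < 1e-12

    def test_zero_dr_rejected(self):
        pooled = PooledHarmonics(p_draws=np.zeros((3, 1)),
                                 q_draws=np.zeros((3, 1)),
                                 weights=np.array([1.0]))
        with pytest.raises(ValueError):
            uncorrected_seasonality(pooled, 0.0)

    def test_period_mean_of_harmonics_is_zero(self, rng):
        # harmonics integrate to zero over one full period
        p, q = rng.normal(size=(2, 4))
        t = np.linspace(0, WEEKS_PER_YEAR, 100_001)[:-1]
        vals = harmonic_curve(p, q, t)
        assert abs(vals.mean()) < 1e-10

    def test_self_correction_identity(self):
        pooled = PooledHarmonics(p_draws=np.full((4, 1), 0.02),
                                 q_draws=np.full((4, 1), -0.01),
                                 weights=np.array([1.0]))
        curve = uncorrected_seasonality(pooled, 0.1, condition="all_visits")
        corrected = corrected_seasonality(curve, curve)
        assert np.max(np.abs(corrected.s)) < 1e-12

    def test_zero_baseline_is_identity(self):
        pooled = PooledHarmonics(p_draws=np.full((4, 1), 0.02),
                                 q_draws=np.zeros((4, 1)),
                                 weights=np.array([1.0]))
        curve = uncorrected_seasonality(pooled, 0.1)
        zero = PooledHarmonics(p_draws=np.zeros((4, 1)),
                               q_draws=np.zeros((4, 1)),
                               weights=np.array([1.0]))
        base = uncorrected_seasonality(zero, 0.1)
        corrected = corrected_seasonality(curve, base)
        np.testing.assert_allclose(corrected.s, curve.s, atol=1e-15)

    def test_correction_is_linear(self, rng):
        # s' + s_all == s exactly
        mk = lambda: PooledHarmonics(
            p_draws=rng.normal(size=(6, 2)), q_draws=rng.normal(size=(6, 2)),
            weights=np.array([1.0]))
        s = uncorrected_seasonality(mk(), 0.2)
        s_all = uncorrected_seasonality(mk(), 0.2)
        corr = corrected_seasonality(s, s_all)
        np.testing.assert_allclose(corr.s + s_all.s, s.s, atol=1e-14)

    def test_grid_mismatch_rejected(self):
        pooled = PooledHarmonics(p_draws=np.zeros((2, 1)),
                                 q_draws=np.zeros((2, 1)),
                                 weights=np.array([1.0]))
        a = uncorrected_seasonality(pooled, 0.1, t=np.arange(10.0))
        b = uncorrected_seasonality(pooled, 0.1, t=np.arange(12.0))
        with pytest.raises(ValueError, match="grid"):
            corrected_seasonality(a, b)


class TestPrevalenceFilter:
    def _curve(self, dr_avg):
        return SeasonalityCurve(t=annual_grid(), s=np.zeros(53), dr_avg=dr_avg)

    def test_strictly_greater_rule(self):
        curves = prevalence_filter([self._curve(1e-5)], threshold=1e-5)
        assert curves[0].suppressed

    def test_above_threshold_retained(self):
        curves = prevalence_filter([self._curve(2e-5)], threshold=1e-5)
        assert not curves[0].suppressed

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError):
            prevalence_filter([self._curve(1e-4)], threshold=0.0)
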