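"""Pooling of harmonic estimates and seasonality-curve construction.

Per-stratum harmonic bases are pooled within an age group with
person-week weights, reparametrized to amplitude/phase, and turned into
the relative seasonal fluctuation

    s(t) = [ sum_n p_n cos(2 n pi t / W) + q_n sin(2 n pi t / W) ] / <DR>,

where ``<DR>`` is the time-average diagnosis rate of the group.  The
corrected curve ``s'(t) = s(t) - s_all(t)`` subtracts the analogous curve
of all medical visits, isolating disease-specific excess over the general
visit rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import WEEKS_PER_YEAR
from .model import PosteriorDraws, hpd_interval
from .strata import DRSeries, SoftStratum, aggregate_dr


@dataclass
class PooledHarmonics:
    """Person-week-weighted harmonic bases of one age group (draw-wise)."""

    p_draws: np.ndarray     # (n_samples, N)
    q_draws: np.ndarray
    weights: np.ndarray     # (n_strata_in_group,)
    age_group: int = -1
    sex: str = ""

    @property
    def p_mean(self) -> np.ndarray:
        return self.p_draws.mean(axis=0)

    @property
    def q_mean(self) -> np.ndarray:
        return self.q_draws.mean(axis=0)


@dataclass
class SeasonalityCurve:
    """Seasonal fluctuation on a weekly annual grid.

    ``s`` is the relative fluctuation as a fraction of the time-average DR
    (multiply by 100 for percent); ``s_draws`` carries posterior
    uncertainty when available.
    """

    t: np.ndarray
    s: np.ndarray
    dr_avg: float
    s_draws: np.ndarray | None = None
    hpd_low: np.ndarray | None = None
    hpd_high: np.ndarray | None = None
    condition: str = ""
    sex: str = ""
    age_group: int = -1
    corrected: bool = False
    suppressed: bool = False

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "condition": self.condition, "sex": self.sex,
            "age_group": self.age_group, "week": self.t,
            "s_pct": 100 * self.s, "dr_avg": self.dr_avg,
            "suppressed": self.suppressed})
        if self.hpd_low is not None:
            out["hpd_low_pct"] = 100 * self.hpd_low
            out["hpd_high_pct"] = 100 * self.hpd_high
        return out


def annual_grid(n_points: int = 53) -> np.ndarray:
    """Integer weeks 0..52 plus nothing beyond the period (53 points in [0, W))."""
    return np.arange(n_points, dtype=float)


def pool_harmonics(draws: PosteriorDraws, strata: list[SoftStratum],
                   age_group: int | None = None) -> PooledHarmonics:
    """Weighted draw-wise pooling of harmonic bases.

    Weights are proportional to each stratum's total person-weeks within
    the selected age group (all strata when ``age_group`` is None) and
    normalized to sum to one.
    """
    by_id = {s.stratum_id: s for s in strata}
    idx, w = [], []
    for i, meta in enumerate(draws.strata_meta):
        st = by_id.get(meta["stratum_id"])
        if st is None:
            continue
        if age_group is not None and st.age_group != age_group:
            continue
        idx.append(i)
        w.append(st.total_person_weeks)
    w = np.asarray(w, dtype=float)
    if w.size == 0 or w.sum() <= 0:
        raise ValueError("zero total pooling weight")
    w = w / w.sum()
    p = np.einsum("i,sin->sn", w, draws.p[:, idx, :])
    q = np.einsum("i,sin->sn", w, draws.q[:, idx, :])
    return PooledHarmonics(p_draws=p, q_draws=q, weights=w,
                           age_group=-1 if age_group is None else age_group,
                           sex=draws.strata_meta[idx[0]]["sex"] if idx else "")


def amplitude_phase(p, q):
    """Amplitude/phase form of harmonic bases.

    ``A = sqrt(p^2 + q^2)`` and ``phi = arctan2(p, q)`` (ordinate ``p``),
    so that ``p cos(x) + q sin(x) = A sin(x + phi)``.  ``A = 0`` maps to
    ``phi = 0`` by convention.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    A = np.hypot(p, q)
    phi = np.where(A > 0, np.arctan2(p, q), 0.0)
    return A, phi


def time_average_dr(series_list: list[DRSeries],
                    span: tuple[int, int] | None = None,
                    holiday_idx=None, flank: int = 2) -> float:
    """Arithmetic mean of the pooled weekly DR of a group of strata.

    Diagnoses and enrollees are summed over strata per week before taking
    the ratio; weeks with no enrollees are excluded.  ``span`` optionally
    restricts to week indices ``[lo, hi]``.  When ``holiday_idx`` is given
    the pooled series is holiday-smoothed first, so reporting dips do not
    bias the normalizer of the relative seasonality.
    """
    agg = aggregate_dr(series_list)
    if span is not None:
        agg = agg.loc[(agg.index >= span[0]) & (agg.index <= span[1])]
    dr = agg["dr"]
    if holiday_idx is not None:
        from .holidays import holiday_smooth
        weeks = agg.index.to_numpy()
        local = [int(np.searchsorted(weeks, w)) for w in holiday_idx
                 if weeks.min() <= w <= weeks.max()]
        dr = pd.Series(holiday_smooth(dr.to_numpy(), local, flank), index=agg.index)
    dr = dr.dropna()
    if dr.empty:
        raise ValueError("no observed weeks in the requested span")
    return float(dr.mean())


def harmonic_curve(p, q, t, period: float = WEEKS_PER_YEAR) -> np.ndarray:
    """Evaluate ``sum_n p_n cos(2 n pi t/W) + q_n sin(2 n pi t/W)``.

    ``p``/``q`` may carry a leading draws axis.
    """
    was_1d = np.asarray(p).ndim == 1
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    t = np.asarray(t, dtype=float)
    n = np.arange(1, p.shape[-1] + 1)
    ang = 2 * np.pi * n[:, None] * t[None, :] / period
    out = p @ np.cos(ang) + q @ np.sin(ang)
    return out[0] if was_1d else out


def uncorrected_seasonality(pooled: PooledHarmonics, dr_avg: float,
                            t=None, condition: str = "",
                            prob: float = 0.95) -> SeasonalityCurve:
    """Relative seasonal fluctuation ``s(t)`` of an age-sex group.

    Division by ``<DR>`` is applied draw-wise; the reported curve is the
    posterior mean with an HPD band.
    """
    if dr_avg <= 0:
        raise ValueError("time-average DR must be positive")
    if t is None:
        t = annual_grid()
    t = np.asarray(t, dtype=float)
    n = np.arange(1, pooled.p_draws.shape[1] + 1)
    ang = 2 * np.pi * n[:, None] * t[None, :] / WEEKS_PER_YEAR
    s_draws = (pooled.p_draws @ np.cos(ang) + pooled.q_draws @ np.sin(ang)) / dr_avg
    s = s_draws.mean(axis=0)
    lo = np.empty_like(s)
    hi = np.empty_like(s)
    if s_draws.shape[0] > 1 and not np.allclose(s_draws.std(axis=0), 0):
        for i in range(t.size):
            lo[i], hi[i] = hpd_interval(s_draws[:, i], prob)
    else:
        lo[:], hi[:] = s, s
    return SeasonalityCurve(t=t, s=s, dr_avg=dr_avg, s_draws=s_draws,
                            hpd_low=lo, hpd_high=hi, condition=condition,
                            sex=pooled.sex, age_group=pooled.age_group)


def corrected_seasonality(curve: SeasonalityCurve,
                          baseline: SeasonalityCurve) -> SeasonalityCurve:
    """Baseline-corrected seasonality ``s'(t) = s(t) - s_all(t)``.

    Both curves must share the same week grid.  When both carry draws of
    equal count the subtraction is applied draw-wise (posteriors from
    separate fits are treated as independent).
    """
    if curve.t.shape != baseline.t.shape or not np.allclose(curve.t, baseline.t):
        raise ValueError("curves are on different week grids")
    s_draws = None
    lo = hi = None
    if (curve.s_draws is not None and baseline.s_draws is not None
            and curve.s_draws.shape == baseline.s_draws.shape):
        s_draws = curve.s_draws - baseline.s_draws
        s = s_draws.mean(axis=0)
        lo = np.empty_like(s)
        hi = np.empty_like(s)
        for i in range(s.size):
            lo[i], hi[i] = hpd_interval(s_draws[:, i])
    else:
        s = curve.s - baseline.s
    return SeasonalityCurve(t=curve.t.copy(), s=s, dr_avg=curve.dr_avg,
                            s_draws=s_draws, hpd_low=lo, hpd_high=hi,
                            condition=curve.condition, sex=curve.sex,
                            age_group=curve.age_group, corrected=True,
                            suppressed=curve.suppressed)


def prevalence_filter(curves: list[SeasonalityCurve],
                      threshold: float = 1e-5) -> list[SeasonalityCurve]:
    """Flag curves whose ``<DR>`` is not strictly above the threshold.

    Suppressed curves stay in the output (for data export) with
    ``suppressed=True``; the rule is strictly-greater, so a curve at
    exactly the threshold is suppressed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    for c in curves:
        c.suppressed = not (c.dr_avg > threshold)
    return curves
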