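"""Harmonic-order selection by the Watanabe-Akaike information criterion.

Candidate harmonic counts N are compared by fitting the full hierarchical
model at each N and summing WAIC (deviance scale, lower is better) over
every condition (and sex) in the run.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .config import ModelConfig
from .model import PosteriorDraws, _student_t_logpdf, build_design, fit_model
from .strata import DRSeries


@dataclasses.dataclass
class WAICResult:
    """WAIC of one fitted model; ``waic = -2 (lppd - p_waic)``."""

    n_harmonics: int
    lppd: float
    p_waic: float
    waic: float
    se: float
    pointwise: np.ndarray


def pointwise_loglik(draws: PosteriorDraws, series_list: list[DRSeries],
                     holiday_idx: set[int] | None = None) -> np.ndarray:
    """Per-draw, per-observation Student-t log likelihood matrix.

    Observations are the (optionally holiday-smoothed) DR values of every
    stratum, concatenated in stratum order; columns align across draws.
    """
    from .holidays import holiday_smooth

    cfg = draws.config
    cols = []
    for i, s in enumerate(series_list):
        y = np.asarray(s.dr, dtype=float)
        if holiday_idx is not None:
            local = [int(w - s.weeks[0]) for w in holiday_idx
                     if s.weeks[0] <= w <= s.weeks[-1]]
            y = holiday_smooth(y, local, flank=cfg.holiday_flank)
        obs = np.isfinite(y)
        t = np.asarray(s.weeks, dtype=float)[obs]
        X = build_design(t, cfg)
        N = cfg.n_harmonics
        coef = np.concatenate([
            draws.alpha[:, i, None], draws.beta[:, i, None],
            draws.gamma[:, i, :],
            np.stack([draws.p[:, i, :], draws.q[:, i, :]], axis=2
                     ).reshape(draws.n_samples, 2 * N) if N else
            np.zeros((draws.n_samples, 0))], axis=1)
        mu = coef @ X.T
        ll = _student_t_logpdf(y[obs][None, :], mu,
                               draws.sigma_y[:, i, None], draws.nu[:, i, None])
        cols.append(ll)
    out = np.concatenate(cols, axis=1)
    if not np.all(np.isfinite(out)):
        bad = np.argwhere(~np.isfinite(out))
        raise ValueError(f"non-finite log likelihood at (draw, obs) {bad[:5]}")
    return out


def waic(loglik: np.ndarray) -> WAICResult:
    """WAIC from a draws x observations log-likelihood matrix.

    ``lppd = sum_i log mean_s exp(ll_si)``; the effective parameter count
    is the variance form ``p_waic = sum_i var_s(ll_si)``; the criterion is
    reported on the deviance scale, with a standard error from the
    pointwise contributions.
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("WAIC needs at least 2 posterior draws")
    S = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    se = float(np.sqrt(ll.shape[1] * waic_i.var(ddof=1))) if ll.shape[1] > 1 else 0.0
    return WAICResult(n_harmonics=-1, lppd=float(lppd_i.sum()),
                      p_waic=float(p_i.sum()), waic=float(waic_i.sum()),
                      se=se, pointwise=waic_i)


def select_harmonics(series_by_condition: dict[str, list[DRSeries]],
                     candidates, config: ModelConfig,
                     holiday_idx: set[int] | None = None):
    """Fit every candidate N and pick the one with the lowest summed WAIC.

    Returns ``(chosen_N, table)`` where the table has one row per
    (candidate, condition) plus the per-candidate sums.  Candidates whose
    fit fails are excluded with a warning.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate harmonic counts supplied")
    rows = []
    sums: dict[int, float] = {}
    for N in candidates:
        cfg = dataclasses.replace(config, n_harmonics=int(N))
        total, total_se2 = 0.0, 0.0
        failed = False
        for cond, series in series_by_condition.items():
            try:
                draws = fit_model(series, cfg, holiday_idx=holiday_idx)
                res = waic(pointwise_loglik(draws, series, holiday_idx=holiday_idx))
            except Exception as exc:   # pragma: no cover - defensive
                warnings.warn(f"candidate N={N}, condition {cond} failed: {exc}")
                failed = True
                break
            rows.append({"N": int(N), "condition": cond, "lppd": res.lppd,
                         "p_waic": res.p_waic, "waic": res.waic, "se": res.se})
            total += res.waic
            total_se2 += res.se ** 2
        if not failed:
            sums[int(N)] = total
            rows.append({"N": int(N), "condition": "__sum__", "lppd": np.nan,
                         "p_waic": np.nan, "waic": total,
                         "se": float(np.sqrt(total_se2))})
    if not sums:
        raise RuntimeError("every candidate failed to fit")
    table = pd.DataFrame(rows)
    chosen = min(sums, key=sums.get)
    return chosen, table
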