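"""Reusable simulation studies exercising the pipeline end to end.

Each experiment generates a synthetic panel under the study conditions,
runs the relevant stages, and returns the recovered quantities next to the
generator's ground truth.  The analysis scripts, the test suite and the
acceptance script all call these functions, so every reported number is
recomputed from scratch.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math

import numpy as np

from .config import ConditionTruth, GeneratorConfig, ModelConfig
from .embedding import group_dispersion, isomap_embed
from .holidays import HolidayCalendar
from .model import fit_model, hpd_interval
from .seasonality import (amplitude_phase, corrected_seasonality,
                          pool_harmonics, time_average_dr,
                          uncorrected_seasonality)
from .selection import pointwise_loglik, select_harmonics, waic
from .simulate import simulate_panel
from .strata import build_hard_strata, compute_dr_series, merge_strata_kmeans

#: Reduced-scale recovery study: 8 soft strata x ~200 weeks x ~5,000
#: enrollees per stratum, one annual harmonic at 15% relative amplitude,
#: New-Year shifts and 50% holiday dips on.
RECOVERY_ALPHA = 0.01
RECOVERY_REL_AMPLITUDE = 0.15
RECOVERY_PHASE = math.pi / 3


def recovery_config(seed: int, n_members: int = 40_000,
                    n_weeks: int = 200) -> GeneratorConfig:
    alpha = RECOVERY_ALPHA
    cond = ConditionTruth(
        code="cond_seasonal", alpha_true=alpha, beta_true=0.0,
        gamma_true=(0.10 * alpha, -0.05 * alpha, 0.05 * alpha),
        harmonics_true=((1, RECOVERY_REL_AMPLITUDE * alpha, RECOVERY_PHASE),))
    return GeneratorConfig(
        n_members=n_members, n_weeks=n_weeks, n_groups=8,
        age_range=(11.0, 20.0), sex_ratio=1.0, conditions=(cond,),
        holiday_dip=0.5, noise="binomial", seed=seed)


def _panel_series(gen: GeneratorConfig, condition: str, k_per_age_group: int):
    cal = HolidayCalendar.us(
        gen.study_start.year,
        (gen.study_start + dt.timedelta(weeks=gen.n_weeks)).year)
    members, claims, truth = simulate_panel(gen, cal)
    hard = build_hard_strata(members)
    soft = merge_strata_kmeans(hard, k_per_age_group, seed=gen.seed)
    soft = [s for s in soft if s.sex == "F"]
    series = [compute_dr_series(s, members, claims, condition) for s in soft]
    hweeks = cal.week_indices(gen.study_start, gen.n_weeks)
    return members, claims, soft, series, hweeks


def run_recovery(seed: int, n_burn: int = 450, n_draws: int = 300) -> dict:
    """Generate-then-fit recovery of the annual harmonic and s(t).

    Returns the posterior-mean peak relative fluctuation (percent), the
    pooled first-harmonic amplitude with its 95% HPD interval, and whether
    the interval covers the generative truth.
    """
    gen = recovery_config(seed)
    members, claims, soft, series, hweeks = _panel_series(gen, "cond_seasonal", 8)
    cfg = ModelConfig(n_harmonics=1, year_boundaries=tuple(gen.year_boundaries),
                      n_burn=n_burn, n_draws=n_draws, thin=2, seed=seed + 1)
    draws = fit_model(series, cfg, holiday_idx=hweeks)
    pooled = pool_harmonics(draws, soft, age_group=1)
    dr_avg = time_average_dr(series, holiday_idx=hweeks)
    curve = uncorrected_seasonality(pooled, dr_avg, condition="cond_seasonal")

    A_draws, _ = amplitude_phase(pooled.p_draws[:, 0], pooled.q_draws[:, 0])
    lo, hi = hpd_interval(A_draws, 0.95)
    truth_A = RECOVERY_REL_AMPLITUDE * RECOVERY_ALPHA
    return {
        "max_s_pct": float(100 * np.max(np.abs(curve.s))),
        "true_rel_amplitude_pct": 100 * RECOVERY_REL_AMPLITUDE,
        "A1_mean": float(A_draws.mean()),
        "A1_hpd": (lo, hi),
        "A1_true": truth_A,
        "A1_covered": bool(lo <= truth_A <= hi),
        "dr_avg": dr_avg,
        "n_strata": len(series),
        "diagnostics": draws.diagnostics,
        "draws": draws,
        "series": series,
        "soft": soft,
        "holiday_weeks": hweeks,
        "curve": curve,
    }


def run_matched_seasonality(seed: int, n_burn: int = 400,
                            n_draws: int = 250) -> dict:
    """Baseline-correction study: a condition whose latent relative
    seasonality equals the all-visit baseline exactly.

    After fitting both and correcting, ``|s'|`` should shrink to the noise
    floor (the shared signal cancels).
    """
    alpha, rel, phase = RECOVERY_ALPHA, RECOVERY_REL_AMPLITUDE, RECOVERY_PHASE
    cond = ConditionTruth(code="cond_matched", alpha_true=alpha,
                          harmonics_true=((1, rel * alpha, phase),))
    allv = ConditionTruth(code="all_visits", alpha_true=10 * alpha,
                          harmonics_true=((1, rel * 10 * alpha, phase),))
    gen = GeneratorConfig(n_members=40_000, n_weeks=200, n_groups=8,
                          age_range=(11.0, 20.0), sex_ratio=1.0,
                          conditions=(cond, allv), holiday_dip=0.5, seed=seed)
    cal = HolidayCalendar.us(2003, 2008)
    members, claims, _ = simulate_panel(gen, cal)
    hard = build_hard_strata(members)
    soft = [s for s in merge_strata_kmeans(hard, 8, seed=seed) if s.sex == "F"]
    hweeks = cal.week_indices(gen.study_start, gen.n_weeks)
    cfg = ModelConfig(n_harmonics=1, year_boundaries=tuple(gen.year_boundaries),
                      n_burn=n_burn, n_draws=n_draws, thin=2, seed=seed + 1)
    curves = {}
    for code in ("cond_matched", "all_visits"):
        series = [compute_dr_series(s, members, claims, code) for s in soft]
        draws = fit_model(series, cfg, holiday_idx=hweeks)
        pooled = pool_harmonics(draws, soft, age_group=1)
        dr_avg = time_average_dr(series, holiday_idx=hweeks)
        curves[code] = uncorrected_seasonality(pooled, dr_avg, condition=code)
    corrected = corrected_seasonality(curves["cond_matched"], curves["all_visits"])
    return {
        "max_s_pct": float(100 * np.max(np.abs(curves["cond_matched"].s))),
        "max_s_corrected_pct": float(100 * np.max(np.abs(corrected.s))),
        "curves": curves,
        "corrected": corrected,
    }


def waic_study_config(seed: int) -> GeneratorConfig:
    """Small panel with one strong annual harmonic for the WAIC study."""
    alpha = 0.01
    cond = ConditionTruth(code="cond_seasonal", alpha_true=alpha,
                          gamma_true=(0.05 * alpha, -0.05 * alpha),
                          harmonics_true=((1, 0.3 * alpha, math.pi / 3),))
    return GeneratorConfig(n_members=8_000, n_weeks=150, n_groups=2,
                           age_range=(11.0, 20.0), sex_ratio=1.0,
                           conditions=(cond,), holiday_dip=0.7, seed=seed)


def run_waic_study(seed: int, candidates=(0, 1, 3), n_burn: int = 250,
                   n_draws: int = 150) -> dict:
    """Harmonic-count selection on data with one true harmonic.

    Returns the summed-WAIC table and the chosen N for one seed.
    """
    gen = waic_study_config(seed)
    members, claims, soft, series, hweeks = _panel_series(gen, "cond_seasonal", 2)
    cfg = ModelConfig(n_harmonics=1, year_boundaries=tuple(gen.year_boundaries),
                      n_burn=n_burn, n_draws=n_draws, thin=2, seed=seed + 1)
    chosen, table = select_harmonics({"cond_seasonal": series}, candidates, cfg,
                                     holiday_idx=hweeks)
    sums = (table[table["condition"] == "__sum__"]
            .set_index("N")[["waic", "se"]])
    return {"chosen": chosen, "table": table,
            "waic_by_N": sums["waic"].to_dict(),
            "se_by_N": sums["se"].to_dict()}


def embedding_features(seed: int, n_per_group: int = 10,
                       jitter: float = 0.05) -> tuple[np.ndarray, list[str]]:
    """Synthetic pooled-harmonic features for the homogeneity study.

    "psychiatric-like" conditions share one harmonic template up to a few
    percent jitter; "infectious-like" conditions keep the template's
    amplitude spectrum but draw random phases, so their curve shapes are
    diverse.
    """
    rng = np.random.default_rng(seed)
    n_harm = 5
    amps = np.array([1.0, 0.5, 0.3, 0.2, 0.1])
    phases = rng.uniform(-np.pi, np.pi, size=n_harm)
    template = np.concatenate([amps * np.sin(phases), amps * np.cos(phases)])
    feats, groups = [], []
    for _ in range(n_per_group):
        feats.append(template * (1 + jitter * rng.standard_normal(2 * n_harm)))
        groups.append("psychiatric-like")
    for _ in range(n_per_group):
        ph = rng.uniform(-np.pi, np.pi, size=n_harm)
        feats.append(np.concatenate([amps * np.sin(ph), amps * np.cos(ph)]))
        groups.append("infectious-like")
    return np.asarray(feats), groups


def run_embedding_study(seed: int, n_neighbors: int = 5) -> dict:
    """Isomap embedding dispersion contrast between the two families."""
    feats, groups = embedding_features(seed)
    res = isomap_embed(feats, n_neighbors=n_neighbors, groups=groups)
    disp = res.dispersion
    return {"dispersion": disp,
            "ratio": disp["psychiatric-like"] / disp["infectious-like"],
            "result": res}
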