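"""Synthetic claims-panel generator with known ground truth.

Emulates the statistical structure of large commercial claims databases:
members enroll in employer-like groups sharing enrollment windows
(asynchronous enrollment), diagnosis rates carry a linear trend, New-Year
level shifts, annual harmonic seasonality, holiday-week dips and count
noise.  Every run serializes its true parameters so downstream recovery can
be tested against a known target.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConditionTruth, GeneratorConfig, WEEKS_PER_YEAR
from .holidays import HolidayCalendar
from .strata import assign_age_group

MEMBER_COLUMNS = ["member_id", "sex", "age_mid", "enroll_start_week", "enroll_end_week"]
CLAIM_COLUMNS = ["member_id", "week", "condition"]


def _group_windows(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_groups`` partially overlapping (start, end) week windows
    jointly covering the full study span."""
    g, n = config.n_groups, config.n_weeks
    if g == 1:
        return np.array([[0, n - 1]])
    # Anchor starts on an even spread over the first part of the span, then
    # jitter; lengths cover 50-100% of the remaining span so windows overlap.
    starts = np.linspace(0, n * 0.4, g).astype(int)
    starts = starts + rng.integers(-3, 4, size=g)
    starts = np.clip(starts, 0, n - int(2 * WEEKS_PER_YEAR))
    starts[0] = 0
    lengths = (rng.uniform(0.5, 1.0, size=g) * (n - starts)).astype(int)
    ends = np.clip(starts + np.maximum(lengths, int(2 * WEEKS_PER_YEAR)) - 1, None, n - 1)
    ends[g - 1] = n - 1
    return np.column_stack([starts, ends])


def sample_enrollment(config: GeneratorConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Sample the member table: enrollment windows, ages and sexes.

    Members are partitioned into ``n_groups`` employer-like clusters; all
    members of a cluster share the same (start, end) window, optionally
    jittered by ``boundary_jitter`` weeks in sub-cohorts to exercise
    soft-boundary merging downstream.
    """
    windows = _group_windows(config, rng)
    group = rng.integers(0, config.n_groups, size=config.n_members)
    starts = windows[group, 0].astype(int)
    ends = windows[group, 1].astype(int)
    if config.boundary_jitter > 0:
        j = config.boundary_jitter
        # Sub-cohorts within a group get a shared small offset on each side.
        sub = rng.integers(0, 3, size=config.n_members)
        offs = rng.integers(-j, j + 1, size=(config.n_groups, 3, 2))
        starts = np.clip(starts + offs[group, sub, 0], 0, config.n_weeks - 1)
        ends = np.clip(ends + offs[group, sub, 1], 0, config.n_weeks - 1)
        ends = np.maximum(ends, starts)
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=config.n_members).round(1)
    sexes = np.where(rng.random(config.n_members) < config.sex_ratio, "F", "M")
    return pd.DataFrame({
        "member_id": np.arange(config.n_members),
        "sex": sexes,
        "age_mid": ages,
        "enroll_start_week": starts,
        "enroll_end_week": ends,
    })


def latent_rate(truth: ConditionTruth, t, config: GeneratorConfig,
                calendar: HolidayCalendar | None = None,
                sex: str | None = None, age_group: int | None = None) -> np.ndarray:
    """Noiseless weekly diagnosis rate at week(s) ``t``.

    ``max(0, alpha + beta t + sum_k 1(t > s_k) gamma_k
    + sum_n A_n sin(2 pi n t / W + phi_n))`` scaled by the holiday dip in
    holiday weeks and by the cell's age/sex multiplier.
    """
    t = np.asarray(t, dtype=float)
    rate = truth.alpha_true + truth.beta_true * t
    bounds = config.year_boundaries
    for s_k, g_k in zip(bounds, truth.gamma_true):
        rate = rate + (t > s_k) * g_k
    for n, amp, phi in truth.harmonics_true:
        rate = rate + amp * np.sin(2 * n * np.pi * t / WEEKS_PER_YEAR + phi)
    if sex is not None and age_group is not None:
        rate = rate * truth.multiplier(sex, age_group)
    rate = np.maximum(rate, 0.0)
    if calendar is not None:
        hweeks = calendar.week_indices(config.study_start, config.n_weeks)
        if hweeks:
            mask = np.isin(t.astype(int), list(hweeks))
            rate = np.where(mask, rate * config.holiday_dip, rate)
    return rate


def generate_claims(members: pd.DataFrame, truths, calendar: HolidayCalendar,
                    config: GeneratorConfig, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, dict]:
    """Draw the weekly claims table and return it with the ground truth.

    For each week and condition the diagnosis count among that week's
    enrollees is drawn from the configured noise model with mean
    ``n_enrolled * latent_rate``; counts are attributed to uniformly sampled
    enrolled members.  One diagnosis event = one row (no deduplication).
    """
    if len(members) == 0:
        raise ValueError("member table is empty")
    n_weeks = config.n_weeks
    starts = members["enroll_start_week"].to_numpy()
    ends = members["enroll_end_week"].to_numpy()
    sexes = members["sex"].to_numpy()
    ages = members["age_mid"].to_numpy()
    age_groups = np.array([assign_age_group(a) if a <= 65 else -1 for a in ages])
    ids = members["member_id"].to_numpy()

    weeks_grid = np.arange(n_weeks)
    # Active-member mask per week (members x weeks).
    active = (starts[:, None] <= weeks_grid) & (weeks_grid <= ends[:, None])
    active_idx = [np.flatnonzero(active[:, w]) for w in range(n_weeks)]

    # Heavy-tailed multiplicative shocks on a random subset of weeks.
    shock = np.ones(n_weeks)
    if config.outlier_rate > 0:
        hit = rng.random(n_weeks) < config.outlier_rate
        shock[hit] = np.exp(rng.standard_t(df=3, size=int(hit.sum()))
                            * config.outlier_scale)

    rows_member, rows_week, rows_cond = [], [], []
    for truth in truths:
        # Cell-specific rates: group members by (sex, age_group) multiplier.
        cell_mult = np.array([truth.multiplier(s, j) if j >= 0 else 1.0
                              for s, j in zip(sexes, age_groups)])
        base = latent_rate(truth, weeks_grid, config, calendar)
        for w in range(n_weeks):
            idx = active_idx[w]
            if idx.size == 0:
                continue
            rate = base[w] * shock[w]
            if rate <= 0:
                continue
            mults = cell_mult[idx]
            # Expected count: sum over enrollees of member-specific rate.
            member_rates = np.minimum(rate * mults, 1.0) if config.noise == "binomial" \
                else rate * mults
            if config.noise == "binomial":
                if np.any(rate * mults > 1.0):
                    raise ValueError(
                        f"latent rate exceeds 1 at week {w} under binomial noise")
                # Uniform-rate fast path when all multipliers equal.
                count = int(rng.binomial(idx.size, float(member_rates.mean())))
            else:
                count = int(rng.poisson(float(member_rates.sum())))
            if count == 0:
                continue
            p = mults / mults.sum()
            chosen = rng.choice(idx, size=count, replace=True, p=p)
            rows_member.append(ids[chosen])
            rows_week.append(np.full(count, w))
            rows_cond.append(np.full(count, truth.code, dtype=object))

    if rows_member:
        claims = pd.DataFrame({
            "member_id": np.concatenate(rows_member),
            "week": np.concatenate(rows_week).astype(int),
            "condition": np.concatenate(rows_cond),
        })
    else:
        claims = pd.DataFrame(columns=CLAIM_COLUMNS).astype(
            {"member_id": int, "week": int, "condition": object})

    truth_payload = {
        "config": _jsonable(config),
        "conditions": [_jsonable(t) for t in truths],
        "year_boundaries": config.year_boundaries,
        "period_weeks": WEEKS_PER_YEAR,
    }
    return claims, truth_payload


def simulate_panel(config: GeneratorConfig, calendar: HolidayCalendar | None = None,
                   seed: int | None = None):
    """End-to-end generation: members, claims and ground truth.

    ``seed`` overrides ``config.seed`` when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if calendar is None:
        calendar = HolidayCalendar.us(
            config.study_start.year,
            (config.study_start + dt.timedelta(weeks=config.n_weeks)).year)
    members = sample_enrollment(config, rng)
    claims, truth = generate_claims(members, config.conditions, calendar, config, rng)
    return members, claims, truth


def write_panel(outdir, members: pd.DataFrame, claims: pd.DataFrame,
                truth: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    members[MEMBER_COLUMNS].to_csv(outdir / "members.csv", index=False)
    claims[CLAIM_COLUMNS].to_csv(outdir / "claims.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dt.date):
        return obj.isoformat()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
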