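"""Configuration objects for the generator, the model and full pipeline runs."""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

#: Annual period of the weekly grid, in weeks.
WEEKS_PER_YEAR = 365.25 / 7.0


@dataclass(frozen=True)
class ConditionTruth:
    """Ground-truth generative parameters for one condition.

    The latent weekly diagnosis rate of a cohort is

        max(0, alpha + beta*t + sum_k 1(t > s_k) gamma_k
               + sum_n A_n sin(2 pi n t / W + phi_n)) * holiday_factor(t)

    with per age-group/sex multiplicative scaling of ``alpha``.

    Parameters
    ----------
    code:
        Condition identifier, e.g. ``"cond_A"``.
    alpha_true:
        Baseline diagnosis rate per person-week (dimensionless).
    beta_true:
        Linear trend, rate change per week.
    gamma_true:
        Level shift at each New-Year boundary, in rate units.
    harmonics_true:
        Sequence of ``(n, A_n, phi_n)`` triplets; amplitudes ``A_n >= 0``,
        phases in ``(-pi, pi]``, period ``WEEKS_PER_YEAR``.
    age_sex_multipliers:
        Optional mapping ``(sex, age_group) -> factor`` scaling the whole
        latent rate for that cell; missing cells default to 1.
    """

    code: str
    alpha_true: float
    beta_true: float = 0.0
    gamma_true: tuple[float, ...] = ()
    harmonics_true: tuple[tuple[int, float, float], ...] = ()
    age_sex_multipliers: tuple[tuple[tuple[str, int], float], ...] = ()

    def __post_init__(self) -> None:
        for n, amp, phi in self.harmonics_true:
            if n < 1:
                raise ValueError(f"harmonic order must be >= 1, got {n}")
            if amp < 0:
                raise ValueError(f"amplitude must be >= 0, got {amp}")
            if not (-math.pi < phi <= math.pi + 1e-12):
                raise ValueError(f"phase must lie in (-pi, pi], got {phi}")

    def multiplier(self, sex: str, age_group: int) -> float:
        for (s, j), m in self.age_sex_multipliers:
            if s == sex and j == age_group:
                return m
        return 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic claims-panel generator.

    The generator emulates the structure of large claims databases:
    employer-like groups enrolling and disenrolling together (asynchronous
    enrollment), age/sex strata, New-Year level shifts, holiday-week dips,
    annual harmonic seasonality on a linear trend, and count noise.
    """

    n_members: int = 10_000
    study_start: dt.date = dt.date(2003, 1, 1)
    n_weeks: int = 208
    n_groups: int = 8
    age_range: tuple[float, float] = (0.0, 65.0)
    sex_ratio: float = 0.5
    conditions: tuple[ConditionTruth, ...] = ()
    holiday_dip: float = 0.5
    noise: str = "binomial"
    outlier_rate: float = 0.0
    outlier_scale: float = 0.3
    boundary_jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups > self.n_members:
            raise ValueError("n_groups may not exceed n_members")
        if self.n_weeks < 2 * WEEKS_PER_YEAR:
            raise ValueError("study span must cover at least two annual periods")
        if not 0.0 <= self.holiday_dip <= 1.0:
            raise ValueError("holiday_dip must lie in [0, 1]")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must lie in [0, 1)")
        if self.noise not in ("binomial", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")

    @property
    def year_boundaries(self) -> list[int]:
        """Week indices of the January-1 boundaries inside the study span.

        A boundary at week ``s`` means level shifts apply to weeks ``t > s``.
        The anchor January 1 itself (week 0) is not a boundary.
        """
        bounds = []
        year = self.study_start.year + 1
        while True:
            delta = (dt.date(year, 1, 1) - self.study_start).days // 7
            if delta >= self.n_weeks:
                break
            bounds.append(delta)
            year += 1
        return bounds


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of the hierarchical Bayesian DR model and its sampler.

    Prior scales marked "auto" are resolved from the data at fit time:
    the half-Cauchy scale for variance-type parameters defaults to 2.5x the
    median per-stratum OLS residual standard deviation, the Laplace scale for
    New-Year shifts to 0.5x the empirical SD of boundary jumps, and the
    normal scale for harmonic bases to the SD of the detrended series.
    """

    n_harmonics: int = 1
    period: float = WEEKS_PER_YEAR
    year_boundaries: tuple[int, ...] = ()
    half_cauchy_multiplier: float = 2.5
    laplace_scale_shape: float = 2.0
    laplace_shift_multiplier: float = 0.5
    shift_scale: float | None = None
    pq_scale_multiplier: float = 1.0
    gp_hyper_scale: float = 1.0
    holiday_flank: int = 2
    n_walkers: int | None = None
    n_burn: int = 500
    n_draws: int = 400
    thin: int = 2
    map_maxiter: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if list(self.year_boundaries) != sorted(set(self.year_boundaries)):
            raise ValueError("year_boundaries must be strictly increasing")


def config_hash(obj) -> str:
    """Stable short hash of a configuration's semantic content."""

    def canon(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {f.name: canon(getattr(x, f.name)) for f in dataclasses.fields(x)}
        if isinstance(x, dt.date):
            return x.isoformat()
        if isinstance(x, (list, tuple)):
            return [canon(v) for v in x]
        if isinstance(x, dict):
            return {str(k): canon(v) for k, v in sorted(x.items())}
        return x

    payload = json.dumps(canon(obj), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_conditions(relative_amplitude: float = 0.15,
                       alpha: float = 0.01) -> tuple[ConditionTruth, ...]:
    """A small default condition set: one seasonal condition plus an
    all-visit-like high-rate condition sharing the same seasonal shape."""
    return (
        ConditionTruth(
            code="cond_seasonal",
            alpha_true=alpha,
            beta_true=0.0,
            gamma_true=(0.1 * alpha, -0.05 * alpha, 0.05 * alpha),
            harmonics_true=((1, relative_amplitude * alpha, math.pi / 3),),
        ),
        ConditionTruth(
            code="all_visits",
            alpha_true=10 * alpha,
            beta_true=0.0,
            gamma_true=(),
            harmonics_true=((1, 0.05 * 10 * alpha, -math.pi / 4),),
        ),
    )
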