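"""Hierarchical Bayesian model of weekly diagnosis-rate series.

One model instance covers every soft stratum of one sex-condition pair.
Each stratum's holiday-smoothed DR series is decomposed into

    y_i(t) = alpha_i + beta_i t + sum_k 1(t > s_k) gamma_ik
             + sum_n [ p_in cos(2 pi n t / W) + q_in sin(2 pi n t / W) ]
             + Student-t noise(sigma_i, nu_i),

with partial pooling: stratum intercepts and slopes are drawn from
skew-normal distributions whose age-group-level locations follow zero-mean
Gaussian-process priors over the age-group index, so neighbouring age
groups share information.  Scale-type parameters get half-Cauchy priors,
New-Year shifts and skew shapes zero-mean Laplace priors (shrinkage), and
harmonic bases zero-mean normals.

Inference: the joint posterior is explored with an affine-ensemble MCMC
sampler (differential-evolution moves), warm-started from the posterior
mode found by L-BFGS — a cheap deterministic stand-in for a full
variational initialization that serves the same purpose of starting the
chains in the typical set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
from scipy import optimize
from scipy.special import gammaln, log_ndtr
from scipy.stats import skewnorm  # noqa: F401  (oracle counterpart; see tests)

from .config import ModelConfig, WEEKS_PER_YEAR
from .holidays import holiday_smooth
from .strata import DRSeries

_LOG2 = np.log(2.0)
_JITTER = 1e-8


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def build_design(t, config: ModelConfig) -> np.ndarray:
    """Design matrix on a week grid.

    Column order: intercept; t; one cumulative indicator per year boundary
    (1 where ``t > s_k``); then ``cos(2 n pi t / W)`` and ``sin(2 n pi t / W)``
    interleaved per harmonic ``n = 1..N``.
    """
    t = np.asarray(t, dtype=float)
    cols = [np.ones_like(t), t]
    for s_k in config.year_boundaries:
        cols.append((t > s_k).astype(float))
    for n in range(1, config.n_harmonics + 1):
        ang = 2 * n * np.pi * t / config.period
        cols.append(np.cos(ang))
        cols.append(np.sin(ang))
    return np.column_stack(cols)


def skew_normal_logpdf(x, loc=0.0, scale=1.0, shape=0.0):
    """Log density of the skew-normal: (2/sigma) phi(z) Phi(h z), z=(x-mu)/sigma.

    ``shape = 0`` recovers the normal density exactly.
    """
    scale = np.asarray(scale, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("scale must be positive")
    z = (np.asarray(x, dtype=float) - loc) / scale
    return (_LOG2 - np.log(scale)
            - 0.5 * (z * z) - 0.5 * np.log(2 * np.pi)
            + log_ndtr(np.asarray(shape, dtype=float) * z))


def _skew_logpdf_raw(x, loc, scale, shape):
    """Unvalidated skew-normal log density; degenerate scales yield non-finite
    values that the posterior maps to -inf."""
    z = (x - loc) / scale
    return (_LOG2 - np.log(scale) - 0.5 * (z * z)
            - 0.5 * np.log(2 * np.pi) + log_ndtr(shape * z))


def gp_covariance(age_idx, scale, length) -> np.ndarray:
    """Exponentiated-quadratic kernel over age-group indices.

    ``K[j, j'] = scale^2 exp(-(j - j')^2 / (2 length^2))``.
    """
    if np.any(np.asarray(scale) <= 0) or np.any(np.asarray(length) <= 0):
        raise ValueError("scale and length must be positive")
    j = np.asarray(age_idx, dtype=float)
    d2 = (j[:, None] - j[None, :]) ** 2
    return scale ** 2 * np.exp(-d2 / (2.0 * length ** 2))


def _student_t_logpdf(x, mu, sigma, nu):
    z2 = ((x - mu) / sigma) ** 2
    return (gammaln((nu + 1) / 2) - gammaln(nu / 2)
            - 0.5 * np.log(nu * np.pi) - np.log(sigma)
            - (nu + 1) / 2 * np.log1p(z2 / nu))


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Minimal-width interval containing ``prob`` of the samples."""
    x = np.sort(np.asarray(samples).ravel())
    n = x.size
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[:n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


# ---------------------------------------------------------------------------
# Posterior specification
# ---------------------------------------------------------------------------

@dataclass
class _FitData:
    """Internal, rescaled view of the series collection."""

    y: np.ndarray          # (S, Wmax) scaled, NaN-padded
    mask: np.ndarray       # (S, Wmax) observed
    X: np.ndarray          # (S, Wmax, C) internal design (centred/scaled t)
    group_idx: np.ndarray  # (S,) age-group position in `groups`
    groups: np.ndarray     # sorted unique age-group indices
    y_scale: float
    t_center: float
    n_boundaries: int
    n_harmonics: int
    # prior scales (internal units)
    hc_scale: float
    b_gamma: float
    pq_scale: float
    b_shape: float
    gp_hyper_scale: float

    @property
    def n_strata(self) -> int:
        return self.y.shape[0]

    @property
    def block(self) -> int:
        return 2 + self.n_boundaries + 2 * self.n_harmonics + 2

    @property
    def n_groups(self) -> int:
        return self.groups.size

    @property
    def ndim(self) -> int:
        return self.n_strata * self.block + 6 * self.n_groups + 4


def _prepare(series_list: list[DRSeries], config: ModelConfig,
             holiday_idx: set[int] | None) -> _FitData:
    S = len(series_list)
    if S == 0:
        raise ValueError("no series supplied")
    ys, ts = [], []
    for s in series_list:
        y = np.asarray(s.dr, dtype=float)
        if holiday_idx is not None:
            local = [int(w - s.weeks[0]) for w in holiday_idx
                     if s.weeks[0] <= w <= s.weeks[-1]]
            y = holiday_smooth(y, local, flank=config.holiday_flank)
        ys.append(y)
        ts.append(np.asarray(s.weeks, dtype=float))
    n_obs = [int(np.isfinite(y).sum()) for y in ys]
    min_needed = 3 * (2 * config.n_harmonics + len(config.year_boundaries) + 2)
    if max(n_obs) < min_needed:
        raise ValueError(
            f"need at least {min_needed} observed weeks in some stratum; "
            f"best stratum has {max(n_obs)}")
    if max(n_obs) == 0:
        raise ValueError("all series are entirely missing")

    all_t = np.concatenate(ts)
    t_center = float(all_t.mean())
    y_scale = float(np.nanmean(np.concatenate(ys)))
    if not np.isfinite(y_scale) or y_scale <= 0:
        y_scale = max(float(np.nanstd(np.concatenate(ys))), 1e-12)

    Wmax = max(len(y) for y in ys)
    C = 2 + len(config.year_boundaries) + 2 * config.n_harmonics
    ypad = np.zeros((S, Wmax))
    mask = np.zeros((S, Wmax), dtype=bool)
    Xpad = np.zeros((S, Wmax, C))
    resid_sds, detrended_sds, jumps = [], [], []
    for i, (y, t) in enumerate(zip(ys, ts)):
        ysc = y / y_scale
        obs = np.isfinite(ysc)
        ypad[i, :len(y)][obs] = ysc[obs]
        mask[i, :len(y)] = obs
        X = build_design(t, config)
        X[:, 1] = (t - t_center) / WEEKS_PER_YEAR   # slope per year, centred
        Xpad[i, :len(y), :] = X
        # empirical scales from per-stratum OLS
        Xo, yo = X[obs], ysc[obs]
        if obs.sum() > X.shape[1] + 2:
            coef, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
            resid_sds.append(float(np.std(yo - Xo @ coef)))
            lin, *_ = np.linalg.lstsq(Xo[:, :2], yo, rcond=None)
            detrended_sds.append(float(np.std(yo - Xo[:, :2] @ lin)))
        for s_k in config.year_boundaries:
            sl = t - t[0]
            pos = s_k - t[0]
            if 4 <= pos <= len(y) - 5:
                before = ysc[int(pos) - 3:int(pos) + 1]
                after = ysc[int(pos) + 1:int(pos) + 5]
                if np.isfinite(before).all() and np.isfinite(after).all():
                    jumps.append(float(np.mean(after) - np.mean(before)))

    hc = config.half_cauchy_multiplier * (np.median(resid_sds) if resid_sds else 0.1)
    hc = max(hc, 1e-3)
    if config.shift_scale is not None:
        b_gamma = max(float(config.shift_scale), 1e-6)
    else:
        b_gamma = config.laplace_shift_multiplier * (
            np.std(jumps) if len(jumps) > 1 else 0.1)
        b_gamma = max(b_gamma, 0.02)
    pq = config.pq_scale_multiplier * (np.median(detrended_sds) if detrended_sds else 0.2)
    pq = max(pq, 0.02)

    ages = np.array([s.age_group for s in series_list])
    groups = np.unique(ages)
    group_idx = np.searchsorted(groups, ages)
    return _FitData(y=ypad, mask=mask, X=Xpad, group_idx=group_idx,
                    groups=groups.astype(float), y_scale=y_scale,
                    t_center=t_center,
                    n_boundaries=len(config.year_boundaries),
                    n_harmonics=config.n_harmonics,
                    hc_scale=float(hc), b_gamma=float(b_gamma),
                    pq_scale=float(pq), b_shape=config.laplace_scale_shape,
                    gp_hyper_scale=config.gp_hyper_scale)


def _log_prob(theta: np.ndarray, d: _FitData) -> np.ndarray:
    """Joint log posterior; vectorized over a leading walker axis."""
    single = theta.ndim == 1
    th = np.atleast_2d(theta)
    M = th.shape[0]
    S, B, G, K, N = d.n_strata, d.block, d.n_groups, d.n_boundaries, d.n_harmonics

    blocks = th[:, :S * B].reshape(M, S, B)
    lin = blocks[:, :, :B - 2]                       # (M, S, C)
    a = blocks[:, :, 0]
    b = blocks[:, :, 1]
    gam = blocks[:, :, 2:2 + K]
    pq = blocks[:, :, 2 + K:2 + K + 2 * N]
    log_sig = blocks[:, :, B - 2]
    log_dnu = blocks[:, :, B - 1]
    hyper = th[:, S * B:S * B + 6 * G].reshape(M, G, 6)
    mu_a, log_sa, h_a = hyper[:, :, 0], hyper[:, :, 1], hyper[:, :, 2]
    mu_b, log_sb, h_b = hyper[:, :, 3], hyper[:, :, 4], hyper[:, :, 5]
    gp = th[:, S * B + 6 * G:]
    log_gs_a, log_gl_a, log_gs_b, log_gl_b = gp.T

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        sig = np.exp(log_sig)
        nu = 2.0 + np.exp(log_dnu)
        sa, sb = np.exp(log_sa), np.exp(log_sb)

        # Student-t likelihood on observed weeks
        mu = np.einsum("swc,msc->msw", d.X, lin)
        ll = _student_t_logpdf(d.y[None], mu, sig[:, :, None], nu[:, :, None])
        lp = np.where(d.mask[None], ll, 0.0).sum(axis=(1, 2))

        # skew-normal priors on stratum intercepts and slopes
        gi = d.group_idx
        lp += _skew_logpdf_raw(a, mu_a[:, gi], sa[:, gi], h_a[:, gi]).sum(axis=1)
        lp += _skew_logpdf_raw(b, mu_b[:, gi], sb[:, gi], h_b[:, gi]).sum(axis=1)

        # GP priors over age-group locations
        for mu_g, lgs, lgl in ((mu_a, log_gs_a, log_gl_a),
                               (mu_b, log_gs_b, log_gl_b)):
            scale = np.exp(lgs)
            length = np.exp(lgl)
            Kmat = (scale[:, None, None] ** 2
                    * np.exp(-(d.groups[None, :, None] - d.groups[None, None, :]) ** 2
                             / (2.0 * length[:, None, None] ** 2)))
            Kmat = Kmat + _JITTER * np.eye(G)[None]
            try:
                L = np.linalg.cholesky(Kmat)
            except np.linalg.LinAlgError:
                return np.full(M, -np.inf) if not single else -np.inf
            sol = np.linalg.solve(L, mu_g[:, :, None])[..., 0]
            lp += (-0.5 * (sol ** 2).sum(axis=1)
                   - np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
                   - 0.5 * G * np.log(2 * np.pi))
            # half-normal hyperpriors (+ log-Jacobian of the log transform)
            s0 = d.gp_hyper_scale
            lp += (_LOG2 - 0.5 * np.log(2 * np.pi * s0 ** 2)
                   - scale ** 2 / (2 * s0 ** 2) + lgs)
            lp += (_LOG2 - 0.5 * np.log(2 * np.pi * s0 ** 2)
                   - length ** 2 / (2 * s0 ** 2) + lgl)

        # half-Cauchy on scale-type parameters (+ Jacobians)
        c = d.hc_scale
        for x, lx in ((sa, log_sa), (sb, log_sb)):
            lp += (_LOG2 - np.log(np.pi * c) - np.log1p((x / c) ** 2) + lx).sum(axis=1)
        lp += (_LOG2 - np.log(np.pi * c) - np.log1p((sig / c) ** 2)
               + log_sig).sum(axis=1)

        # Laplace shrinkage on shapes and shifts
        bh = d.b_shape
        lp += (-np.log(2 * bh) - np.abs(h_a) / bh).sum(axis=1)
        lp += (-np.log(2 * bh) - np.abs(h_b) / bh).sum(axis=1)
        if K:
            bg = d.b_gamma
            lp += (-np.log(2 * bg) - np.abs(gam) / bg).sum(axis=(1, 2))

        # zero-mean normal on harmonic bases
        if N:
            sp = d.pq_scale
            lp += (-0.5 * (pq / sp) ** 2
                   - 0.5 * np.log(2 * np.pi * sp ** 2)).sum(axis=(1, 2))

        # nu = 2 + delta, delta ~ Gamma(2, rate 0.1) (+ Jacobian)
        delta = nu - 2.0
        shape_g, rate_g = 2.0, 0.1
        lp += (shape_g * np.log(rate_g) - gammaln(shape_g)
               + (shape_g - 1) * np.log(delta) - rate_g * delta
               + log_dnu).sum(axis=1)

    lp = np.where(np.isfinite(lp), lp, -np.inf)
    return lp[0] if single else lp


def _initial_point(d: _FitData) -> np.ndarray:
    """OLS-based starting point for the MAP optimization."""
    S, B, G = d.n_strata, d.block, d.n_groups
    x0 = np.zeros(d.ndim)
    a_by_group = [[] for _ in range(G)]
    b_by_group = [[] for _ in range(G)]
    for i in range(S):
        obs = d.mask[i]
        Xo, yo = d.X[i][obs], d.y[i][obs]
        coef, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
        resid = yo - Xo @ coef
        blk = slice(i * B, (i + 1) * B)
        x0[blk.start:blk.start + B - 2] = coef
        x0[blk.start + B - 2] = np.log(max(float(np.std(resid)), 1e-4))
        x0[blk.start + B - 1] = np.log(18.0)   # nu ~ 20
        a_by_group[d.group_idx[i]].append(coef[0])
        b_by_group[d.group_idx[i]].append(coef[1])
    base = S * B
    for g in range(G):
        avals = np.array(a_by_group[g] or [0.0])
        bvals = np.array(b_by_group[g] or [0.0])
        x0[base + 6 * g + 0] = avals.mean()
        x0[base + 6 * g + 1] = np.log(max(avals.std(), 0.05))
        x0[base + 6 * g + 3] = bvals.mean()
        x0[base + 6 * g + 4] = np.log(max(bvals.std(), 0.05))
    x0[base + 6 * G:] = np.log(0.5)
    return x0


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Flattened posterior samples of one sex-condition model, natural scale.

    Stratum-level arrays have shape ``(n_samples, n_strata, ...)``; the DR
    decomposition parameters (alpha, beta, gamma, p, q, sigma_y) are on the
    raw DR scale with beta per week.  Hyperparameter draws are kept on the
    internal standardized scale (they parametrize the internal priors).
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sigma_y: np.ndarray
    nu: np.ndarray
    hyper: np.ndarray            # (n_samples, G, 6) internal scale
    gp: np.ndarray               # (n_samples, 4) log scale/length pairs
    strata_meta: list = field(default_factory=list)
    age_groups: np.ndarray = field(default_factory=lambda: np.array([]))
    config: ModelConfig | None = None
    diagnostics: dict = field(default_factory=dict)
    y_scale: float = 1.0
    t_center: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_strata(self) -> int:
        return self.alpha.shape[1]


def _unpack_draws(chain: np.ndarray, d: _FitData, config: ModelConfig,
                  series_list, diagnostics: dict) -> PosteriorDraws:
    M = chain.shape[0]
    S, B, G, K, N = d.n_strata, d.block, d.n_groups, d.n_boundaries, d.n_harmonics
    blocks = chain[:, :S * B].reshape(M, S, B)
    a = blocks[:, :, 0]
    b = blocks[:, :, 1]
    beta = d.y_scale * b / WEEKS_PER_YEAR
    alpha = d.y_scale * a - beta * d.t_center
    gamma = d.y_scale * blocks[:, :, 2:2 + K]
    # harmonic columns are interleaved (cos_1, sin_1, cos_2, sin_2, ...)
    p = d.y_scale * blocks[:, :, 2 + K:2 + K + 2 * N:2]
    q = d.y_scale * blocks[:, :, 2 + K + 1:2 + K + 2 * N:2]
    sigma_y = d.y_scale * np.exp(blocks[:, :, B - 2])
    nu = 2.0 + np.exp(blocks[:, :, B - 1])
    hyper = chain[:, S * B:S * B + 6 * G].reshape(M, G, 6)
    gp = chain[:, S * B + 6 * G:]
    meta = [{"stratum_id": s.stratum_id, "sex": s.sex, "age_group": s.age_group,
             "weeks": (int(s.weeks[0]), int(s.weeks[-1]))} for s in series_list]
    return PosteriorDraws(alpha=alpha, beta=beta, gamma=gamma, p=p, q=q,
                          sigma_y=sigma_y, nu=nu, hyper=hyper, gp=gp,
                          strata_meta=meta,
                          age_groups=np.array([s.age_group for s in series_list]),
                          config=config, diagnostics=diagnostics,
                          y_scale=d.y_scale, t_center=d.t_center)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_model(series_list: list[DRSeries], config: ModelConfig,
              holiday_idx: set[int] | None = None) -> PosteriorDraws:
    """Fit the joint hierarchical model to one sex-condition series collection.

    Parameters
    ----------
    series_list:
        One :class:`DRSeries` per soft stratum (same sex and condition).
    config:
        Model and sampler settings; ``config.seed`` drives all randomness.
    holiday_idx:
        Optional global week indices of holiday weeks; when given, each
        series is holiday-smoothed before fitting (the observation model
        applies to the smoothed series).
    """
    d = _prepare(series_list, config, holiday_idx)
    rng = np.random.default_rng(config.seed)

    # --- posterior mode (warm start) ---
    x0 = _initial_point(d)
    neg = lambda x: -float(_log_prob(x, d))
    res = optimize.minimize(neg, x0, method="L-BFGS-B",
                            options={"maxiter": config.map_maxiter,
                                     "maxfun": 20 * config.map_maxiter})
    x_map = res.x if np.isfinite(res.fun) else x0

    # --- ensemble MCMC ---
    ndim = d.ndim
    nwalkers = config.n_walkers or max(2 * ndim + 4, 64)
    if nwalkers % 2:
        nwalkers += 1
    spread = np.maximum(0.05 * np.abs(x_map), 0.01)
    p0 = x_map[None, :] + spread[None, :] * rng.standard_normal((nwalkers, ndim))
    lp0 = _log_prob(p0, d)
    bad = ~np.isfinite(lp0)
    tries = 0
    while bad.any() and tries < 50:
        p0[bad] = x_map[None, :] + 0.5 * spread[None, :] * rng.standard_normal(
            (int(bad.sum()), ndim))
        lp0 = _log_prob(p0, d)
        bad = ~np.isfinite(lp0)
        tries += 1

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, _log_prob, args=(d,),
                                    vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(config.seed % (2 ** 31)).get_state()
    state = sampler.run_mcmc(p0, config.n_burn, progress=False,
                             skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, config.n_draws, progress=False,
                     skip_initial_state_check=True)
    chain = sampler.get_chain(thin=config.thin, flat=True)

    diagnostics = {
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        "n_walkers": int(nwalkers),
        "n_steps_kept": int(config.n_draws),
        "map_converged": bool(res.success),
        "map_logpost": float(-res.fun) if np.isfinite(res.fun) else None,
    }
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau = sampler.get_autocorr_time(quiet=True)
        diagnostics["autocorr_time_mean"] = float(np.nanmean(tau))
        diagnostics["ess_est"] = float(nwalkers * config.n_draws
                                       / max(np.nanmean(tau), 1.0))
    except Exception:   # pragma: no cover - emcee raises on short chains
        diagnostics["autocorr_time_mean"] = None
    return _unpack_draws(chain, d, config, series_list, diagnostics)


def posterior_expectation_curve(draws: PosteriorDraws, stratum: int, t,
                                prob: float = 0.95):
    """Pointwise posterior mean and HPD band of the fitted DR curve.

    Returns ``(mean, lo, hi)`` arrays over the week grid ``t``.
    """
    if draws.n_samples == 0:
        raise ValueError("no posterior draws")
    t = np.asarray(t, dtype=float)
    cfg = draws.config
    X = build_design(t, cfg)
    K, N = len(cfg.year_boundaries), cfg.n_harmonics
    coef = np.concatenate([
        draws.alpha[:, stratum, None], draws.beta[:, stratum, None],
        draws.gamma[:, stratum, :],
        np.stack([draws.p[:, stratum, :], draws.q[:, stratum, :]], axis=2
                 ).reshape(draws.n_samples, 2 * N) if N else
        np.zeros((draws.n_samples, 0)),
    ], axis=1)
    curves = coef @ X.T
    mean = curves.mean(axis=0)
    if np.allclose(curves.std(axis=0), 0):
        return mean, mean.copy(), mean.copy()
    lo = np.empty_like(mean)
    hi = np.empty_like(mean)
    for i in range(t.size):
        lo[i], hi[i] = hpd_interval(curves[:, i], prob)
    return mean, lo, hi
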