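# cyclemetry

Hierarchical Bayesian estimation of annual seasonality in weekly disease
diagnosis rates from asynchronously enrolled claims cohorts.

## The problem

Large claims panels (commercial insurance databases, national health
registers) are the only data dense enough to measure how diagnosis rates
of a condition oscillate over the year.  But they are biased instruments:
cohorts enter and leave the panel at different times (so naive trends
confound composition with dynamics), diagnosis rates jump at New-Year
boundaries when coding practices change, holiday weeks show sharp
reporting dips, and counts are noisy.  `cyclemetry` estimates the annual
cycle while modelling these biases explicitly, and ships a synthetic
claims generator with known ground truth so every stage is testable
without proprietary data.

## The model

Members are grouped into population strata — cohorts sharing sex, age
group (0–10, 11–20, 21–30, 31–40, 41–50, 51–65; over-65 excluded) and an
approximately shared enrollment window, obtained by weighted K-means on
window boundaries.  For stratum *i* in age group *j*, the
holiday-smoothed weekly diagnosis rate is decomposed as

    y_ij(t) = α_ij + β_ij·t + Σ_k 1(t>s_k)·γ_ijk
            + Σ_{n=1}^{N} [ p_ijn·cos(2nπt/W) + q_ijn·sin(2nπt/W) ] + ε_ij

with period W = 365.25/7 weeks and s_k the January-1 week indices.
Intercepts and slopes get skew-normal priors whose age-group-level
locations are tied by zero-mean Gaussian-process priors over the age
index; scales are half-Cauchy, New-Year shifts and skew shapes are
Laplace-shrunk, harmonic bases are zero-mean normal, and the observation
model is a Student-t on the holiday-smoothed series.  The joint posterior
of one sex-condition model is sampled by ensemble MCMC warm-started from
the posterior mode.

Downstream, harmonic bases are pooled across strata with person-week
weights (p̄_jn = Σ_i w_i p_ijn), reparametrized to amplitude/phase
(A = √(p²+q²), φ = arctan2(p, q)), and turned into the relative seasonal
fluctuation s(t) = (Σ_n p̄_n cos + q̄_n sin) / ⟨DR⟩ in percent of the
time-average rate.  The corrected curve s′(t) = s(t) − s_all(t) subtracts
the all-visit baseline of the matched age-sex group.  The harmonic count
N is chosen by summed WAIC, and curve shapes are compared across
conditions by Isomap embedding of the pooled harmonic vectors.

## Worked example

Recover a known 15% annual amplitude from a biased synthetic panel
(8 employer-like cohorts, ~5,000 enrollees each, 200 weeks, New-Year
shifts and 50% holiday dips on, binomial noise):

```bash
python analysis/04_recovery_study.py 1
```

prints

```
replicate 0: peak |s| = 14.63% (truth 15%), A1 = 0.00155 HPD [0.00146, 0.00164] covers truth: True
replicate 1: peak |s| = 14.38% (truth 15%), A1 = 0.00152 HPD [0.00142, 0.00161] covers truth: True
replicate 2: peak |s| = 14.41% (truth 15%), A1 = 0.00153 HPD [0.00143, 0.00161] covers truth: True
mean peak |s| = 14.47% over 3 replicates
```

Peak |s| is the maximum of the posterior-mean relative fluctuation curve
— how far the weekly diagnosis rate swings from its annual mean.  A1 is
the pooled first-harmonic amplitude on the rate scale (truth
0.15 × 0.01 = 0.0015) with its 95% highest-posterior-density interval.

The other numbered scripts under `analysis/` run the remaining stages:
panel generation, strata construction, the end-to-end fit with corrected
curves, WAIC harmonic selection (`N=0` ranks worst on data with one true
harmonic; `N=3` does not beat `N=1`), and the Isomap homogeneity study
(shared-template condition families embed ~50× tighter than random-phase
families).  The `cyclemetry` CLI exposes the same stages
(`simulate`, `strata`, `smooth`, `run`, `embed`).

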