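# Methods

## Problem and model

Weekly diagnosis rates (DR: diagnoses divided by enrollees in a week)
estimated from claims panels confound disease dynamics with enrollment
composition: cohorts enter and leave the panel at different times
(asynchronous enrollment), coding practice jumps at New-Year boundaries,
and holiday weeks show sharp reporting dips.  The package estimates annual
seasonality while accounting for these biases by modelling each
*population stratum* — a cohort sharing sex, age group and (approximately)
an enrollment window — separately but not independently.

For stratum *i* in age group *j* the holiday-smoothed DR series is
decomposed as

    y_ij(t) = α_ij + β_ij t                          (linear trend)
            + Σ_k 1(t > s_k) γ_ijk                   (New-Year level shifts)
            + Σ_{n=1..N} p_ijn cos(2nπt/W) + q_ijn sin(2nπt/W)   (seasonality)
            + ε_ij(t),

with the annual period W = 365.25/7 weeks and boundaries s_k at January 1
of each study year.  The error term is realized as the Student-t
observation model below — the robust likelihood and the residual are one
and the same here, which is the simplest reading consistent with the
decomposition.  The equivalent amplitude/phase form per harmonic is
A = √(p² + q²), φ = arctan2(p, q), so p·cos + q·sin = A·sin(2nπt/W + φ).

### Priors and hierarchy

* Intercepts and slopes: `α_ij ~ SkewNormal(μ^α_j, σ^α_j, h^α_j)` and
  likewise for β.  The skew-normal density is (2/σ)·φ(z)·Φ(hz) with
  z = (x−μ)/σ; h = 0 recovers the normal exactly.
* Age-group locations `μ^α_j`, `μ^β_j` follow zero-mean Gaussian-process
  priors over the age-group index with exponentiated-quadratic kernels
  `k(j,j′) = s²·exp(−(j−j′)²/(2ℓ²))`, so neighbouring age groups share
  trend information.  Kernel scale and length get half-normal(1)
  hyperpriors: improper flat hyperpriors destabilize sampling in a model
  of this dimension, and a unit half-normal is weakly informative on the
  standardized scale the model is fitted on.
* Scale-type parameters (σ^α_j, σ^β_j, σ^y_ij): half-Cauchy with scale
  2.5× the median per-stratum OLS residual SD (configurable multiplier) —
  a weakly-informative default anchored to the data's own noise level.
* Skew shapes h^·_j: zero-mean Laplace with scale b_h = 2, preventing the
  shape from competing with the scale (a large shape can mimic a large
  scale and stall the sampler).
* New-Year shifts γ: zero-mean Laplace with scale 0.5× the empirical SD of
  boundary jumps (floor 0.02 on the standardized scale), encoding the
  belief that shifts must not mask the linear trend.  An explicit
  `shift_scale` override exists; driving it toward 0 collapses the shifts
  and lets the slope absorb the drift (tested).
* Harmonic bases p, q: zero-mean normal with scale set to the SD of the
  detrended series.
* Observation model: `HolidaySmooth[y_ij(t)] ~ StudentT(μ^y_ij(t), σ^y_ij,
  ν_ij)` with ν = 2 + Δ, Δ ~ Gamma(2, rate 0.1): the truncation keeps the
  variance finite while still allowing heavy tails that absorb outlier
  weeks.

### Internal standardization

The model is fitted on `ỹ = y / ȳ` (ȳ = mean observed DR across strata)
with the time axis centred and expressed in years.  This puts intercepts
near 1 and slopes, shifts and harmonics on comparable scales, which the
optimizer and the sampler both need.  Reported stratum-level draws are
transformed back to the natural DR scale (slope per week); hyperparameter
draws stay on the internal scale since they parametrize internal priors.

### Inference

The joint posterior over all strata and hyperparameters of one
sex-condition model is sampled with an affine-ensemble MCMC sampler
(`emcee`, differential-evolution and snooker moves, 80/20 mix), with
walkers initialized in a small ball around the posterior mode found by
L-BFGS from per-stratum OLS starting values.  The mode-finding step plays
the same role as a variational warm start: chains begin inside the
typical set rather than burning in from a diffuse cloud.  Defaults:
walkers = 2·ndim + 4 (minimum 64), 500 warm-up steps, 400 kept steps,
thinning 2, all seeded.  Diagnostics recorded per fit: mean acceptance
fraction, integrated autocorrelation estimate, derived effective sample
size and the MAP value.  These are report-only; no convergence gate is
applied.

### Downstream quantities

* Pooling: within an age group, harmonic bases are pooled draw-wise with
  weights proportional to stratum person-weeks, normalized to 1 —
  `p̄_jn = Σ_i w_i p_ijn` — so pooled quantities carry posterior
  uncertainty.
* Time-average DR ⟨DR⟩: diagnoses and enrollees are summed over the
  group's strata per week before taking the ratio; the mean is taken over
  observed weeks.  The pooled series is holiday-smoothed before averaging
  so that reporting dips do not bias the normalizer (the dips are
  artifacts the pipeline explicitly removes everywhere else).
* Uncorrected seasonality `s(t) = Σ_n p̄_n cos(2nπt/W) + q̄_n sin(2nπt/W)
  divided by ⟨DR⟩`, evaluated on integer weeks 0..52 and reported in
  percent.  Division is draw-wise; curves report the posterior mean with a
  95% minimal-width (HPD) band.
* Corrected seasonality `s′(t) = s(t) − s_all(t)`, where s_all is the
  same pipeline run on an all-visit pseudo-condition for the *matched*
  sex and age group.  Matched grouping was chosen because corrected
  curves are presented per age-sex group; a region-level baseline is the
  plausible alternative and remains possible by passing any baseline
  curve.
* Display filter: curves with ⟨DR⟩ not strictly above 1×10⁻⁵ are flagged
  suppressed (kept in data outputs).
* Harmonic-order selection: WAIC with the variance form of the effective
  parameter count, on the deviance scale (lower is better), summed over
  the conditions (and sexes) in a run.  Desk-scale candidate set {0, 1, 3}
  rather than a large-N sweep: the synthetic truth has few harmonics, so
  the interesting contrasts are "none", "right order" and "overfit".
* Embedding: pooled posterior-mean harmonic vectors (p̄₁..p̄₅, q̄₁..q̄₅),
  aggregated over age-sex groups by person-week weight, embedded with
  Isomap (k-NN geodesics + classical MDS, default k = 5, deterministic
  axis-sign convention).  Within-group mean pairwise distance quantifies
  family homogeneity.

## Synthetic-data generator

The generator is the study's data source and defines the test conditions:

* Employer-like groups share exact enrollment windows (drawn to overlap
  and jointly cover the span); an optional ±jitter splits each group into
  sub-cohorts to exercise soft-boundary merging.
* The latent weekly rate is the additive decomposition above truncated at
  0 (identity link, mirroring the additive model), times a holiday-dip
  factor in holiday weeks and a per-cell age/sex multiplier.
* Counts: binomial(enrollees, rate) by default (the natural claims-count
  mechanism), Poisson optional; an outlier switch applies heavy-tailed
  multiplicative shocks (exp of scaled Student-t(3)) to random weeks —
  the tails the Student-t likelihood is meant to absorb.  The robust
  observation model is an inference choice, not a data-generating claim.
* One diagnosis event = one claim row; deduplication is a reader option.
* Age bins 0–10, …, 51–65; members over 65 are excluded from strata.

What the generator does *not* emulate: ICD-style code vocabularies,
geographic structure, member-level disease correlation (counts are
attributed to members uniformly), re-enrollment gaps, or age-group
transitions mid-study.  Passing recovery tests therefore show the
estimator is consistent under the model's own bias structure, not that it
is robust to every idiosyncrasy of real claims data.

## Holiday handling

The US profile contains the 10 federal holidays observed 2003–2014 plus
Easter and Good Friday (Easter by the anonymous Gregorian computus);
other profiles load from YAML.  A week is a holiday week if it contains a
holiday date (optionally dilated ±1 week).  The holiday-smooth transform
replaces each holiday-week value by the mean of the nearest m = 2
non-holiday, non-missing weeks on each side (fewer at edges).  Because
replacements depend only on non-holiday weeks, the transform is
idempotent and leaves non-holiday weeks bit-identical.  The flanking-mean
window is a declared operationalization of "averaging around holidays":
dips are confined to the holiday week itself in the data this emulates.

## Strata construction

Hard strata are distinct (sex, age group, start, end) keys.  Soft strata
merge hard strata by K-means in the 2-D (start, end) space, member counts
as sample weights, run independently per (sex, age group) cell with
seeded k-means++ initialization; k is reduced with a warning when a cell
has fewer distinct windows.  Merged windows are member-weighted mean
boundaries rounded to the week grid.  Weeks are 0-based 7-day bins
anchored at the study start date; a member's age group is fixed at the
age at mid-enrollment.

## Problem sizes

All studies run at desk scale, chosen so the full analysis reproduces on
a single CPU: recovery uses 8 soft strata × 200 weeks × ~5,000 enrollees
per stratum with ~450 + 300 ensemble steps; the WAIC study uses 2 strata
× 150 weeks panels; the embedding study works on 20 feature vectors.
The 3-replicate recovery subset is the default gate; the 20-replicate
version of the same study is a long-running job.

## Numerical choices and edge cases

* Degenerate prior scales (underflowing exp) map to −inf posterior rather
  than raising, so the optimizer and sampler can traverse freely.
* GP covariances carry a 1e-8 jitter on the diagonal.
* A = 0 maps to φ = 0 by convention; zero enrollee weeks yield missing DR
  (never division by zero); an entirely-holiday series is an error.
* K-means ties are broken by the seeded initialization; assignments are
  deterministic given the seed.
* HPD intervals are minimal-width intervals of the sorted draws.

## Known limitations

* The ensemble sampler mixes more slowly than gradient-based HMC in high
  dimension; effective sample sizes are modest at the default budgets,
  and HPD intervals can be slightly too narrow in hard corners of the
  posterior.  Budgets are configurable where more precision is needed.
* Fits cover one sex-condition collection at a time; very large stratum
  counts would need longer chains (more walkers) than the defaults.
* The corrected curve subtracts posteriors from two independent fits,
  treating them as independent; any correlation induced by shared data
  (the all-visit counts include the condition's claims) is ignored.
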