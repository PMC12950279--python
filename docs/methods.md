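# Methods

## The trajectory model and its assumptions

The normative model at each in-mask voxel is a linear mixed-effects model
of modulated gray-matter volume against time since a subject's first scan:
fixed intercept and slope per voxel, subject-level random intercept and
slope with shared 2×2 covariance Σ_b, and i.i.d. Gaussian residuals σ²_ε.
The model assumes (i) control decline is linear over the observation window
(a few years, where linearity is a reasonable first-order description of
normative aging), (ii) subject effects are shared across voxels in the
generator but estimated independently per voxel in the analysis, and (iii)
residuals are homoscedastic within a voxel.

Fixed effects are estimated per voxel by closed-form GLS given the variance
components. Components are estimated by REML (statsmodels `MixedLM`), in
one of two modes:

- `pooled` (default): REML on an evenly spaced sample of 40 in-mask voxels,
  averaged. On desk-scale grids the generator's components genuinely are
  shared across voxels, and pooling removes per-voxel estimation noise.
- `voxel`: REML at every voxel. Faithful but slow; intended for small grids.

Degenerate voxels (near-zero within-subject residual variance, or REML
non-convergence) fall back to a method-of-moments estimator: between-subject
covariance of per-subject OLS coefficients minus the mean sampling
covariance, eigenvalue-clipped to positive semidefinite. Both fallbacks are
logged.

## Subject posteriors and deviation scores

A subject's first two scans (both required at global CDR + NACC-FTLD ≤ 0.5;
configurable to 0 for the asymptomatic-only sensitivity analysis) update
the zero-mean random-effect prior by conjugacy in the innovation form
K = Σ_b Xᵀ(X Σ_b Xᵀ + σ²I)⁻¹, which remains well-defined in both degenerate
limits: Σ_b → 0 pins the subject to the population trajectory, σ² → 0 makes
the posterior interpolate the two observations. A joint refit of the
control model including the subject's pair would change the estimates only
at O(1/n_controls); the two-stage conjugate update is therefore the single
implemented mode.

The posterior predictive at time t is Gaussian with mean on the
subject-specific line and variance xᵀΣ_post x + σ²_ε — parameter
uncertainty plus residual noise, so predictive SD is minimized near the
pair's center of information and grows quadratically away from it. Scans
with index ≥ 2 are scored voxel-wise with erf((y−μ)/(s√2)); the predictor
pair itself is never scored (enforced as a protocol error). Voxels with
zero predictive SD are excluded from maps and counts, and logged. Cluster
volume counts voxels with erf ≤ threshold (≤, matching the W-map rule;
thresholds in (−1, 0), default sweep −0.7, −0.8, −0.9, −0.99, −0.999) times
voxel volume, with no connected-component requirement. Positive erf values
are retained in maps but never counted.

## W-score and ROI comparators

The W model is ordinary least squares of voxel value on age, TIV, and
reference-coded scanner indicators, fit cross-sectionally on one scan per
control (the first — using all scans would double-count subjects). Sex is
deliberately excluded from the design; sex effects are examined by
stratified survival models instead. With a single scanner the indicator
columns are dropped; an unknown scanner level at scoring time is a hard
error rather than silent remapping. Residual SD uses the OLS degrees of
freedom (n − p). W ≤ −σ counting uses ≤, uniformly with the erf rule. ROI
metrics are plain means over atlas labels; the synthetic atlas ships two
disjoint composite labels standing in for frontal and temporal lobes.
W-map and ROI metrics are computed at the same follow-up scans (index ≥ 2)
as the BLME metrics.

## Survival stage

Counting-process episodes: each included scan (index ≥ 2, time strictly
before the subject's event/censoring time) opens an episode carrying the
metric measured at its start (last observation carried forward); the final
episode ends at the conversion visit (event) or last observation
(censored). Converters whose conversion precedes their first usable scan
are excluded and logged. The time axis is study time (years since first
scan) with age at episode start as covariate — the alternative
age-as-time-axis parameterization was considered and rejected as the
default because age enters more transparently as a covariate; TIV is added
for ROI metrics. The metric is z-scored (population SD) over all
observations entering a given model, so per-gene or per-sex models
standardize within their subset and hazard ratios read per within-subset SD.

Partial-likelihood maximization uses lifelines' `CoxTimeVaryingFitter`
(Efron ties). Heavily zero-inflated cluster-volume predictors can make the
full Newton step overshoot; the fit retries deterministically with damped
steps (0.25, 0.1, 0.02) before raising. A constant covariate is a hard
error: it would otherwise yield a silently meaningless hazard ratio.

## Horizon classification

Months are years × 12 throughout; no calendar arithmetic. Converters keep
the scan closest to the 27-month (24 + 3 buffer) pre-conversion boundary
among scans strictly before conversion and within the window; an earlier
scan wins exact ties. Non-converters need a scan ≥ 24 months before last
observation and keep the qualifying scan closest to that boundary. AUC is
the Mann-Whitney pair statistic (ties ½); variance, CIs (normal, clipped to
[0, 1]), and the paired test use DeLong structural components. Metric
orientation is explicit per metric — larger cluster volumes score toward
conversion, smaller ROI volumes do — with no automatic flipping.

## The synthetic cohort generator

The generator emulates the longitudinal structure the analysis assumes:
controls decline linearly with subject-level random intercepts/slopes;
a configurable fraction of carriers additionally accelerate
(`acceleration_magnitude`, an extra negative slope) inside a spherical
voxel cluster with randomized center after a Gaussian change-point onset;
conversion is recorded at the first scheduled visit (index ≥ 2) at or after
onset + lag, as CDR is ascertained at visits; subjects whose conversion
falls beyond the window remain non-converters (with presymptomatic
acceleration — deliberately, since that heterogeneity is what makes the
survival analysis non-trivial). Visit times jitter around a regular grid.

Default conditions emulate a familial-FTLD observational cohort: baseline
age 47.8 (SD 12.5) years truncated to [18, 90], 56.8% female, three scanner
platforms, carrier gene mix ≈ 41:32:27 (C9orf72:GRN:MAPT), ~14.5% of
carriers questionably symptomatic (CDR 0.5) at baseline, ~annual visits
(1.1 ± 0.15 years, 5 scans), and ~10% of carriers converting within the
window (prop_converters = 0.15 with onset 2.5 ± 1.5 years and lag 1 year).
Voxel values sit on an arbitrary but internally consistent modulated
gray-matter scale: baseline 0.60 per voxel with ±5% smooth fixed spatial
variation, subject intercept SD 0.05, slope −0.006 ± 0.003 per year
(~1%/year normative loss), residual SD 0.02, acceleration −0.04 per year in
a radius-3-voxel cluster, 2-mm isotropic voxels on a 12³ grid. Age, sex and
TIV have no effect on voxel values by default (configurable), keeping null
calibration clean. Values are clipped at zero (modulated volumes are
non-negative); with default scales the clip is never active, but configs
that push the mean toward zero will bias trajectories.

Randomness uses one root seed with per-subject substreams keyed by a SHA-256
hash of the subject id, so enlarging a cohort never reshuffles existing
subjects; gene labels likewise come from per-subject streams. Identical
config and seed give bit-identical cohorts. Each subject's ground truth
(random effects, onset, cluster center) is recorded on the in-memory series
for recovery tests; it is not serialized.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: brain anatomy and spatial autocorrelation
(smoothing), scanner-specific intensity effects, registration error,
nonlinear or gene-specific trajectory shapes, dropout that is informative
of disease, and measurement of CDR itself. Per-group parameter overrides
are possible by simulating groups separately; no gene-specific defaults are
prescribed.

## Numerical choices

- Closed-form vs oracle comparisons at 1e-4 relative tolerance; erf via
  `scipy.special.erf`.
- z-scoring uses the population SD (output SD exactly 1).
- GLS degenerate limit (σ² = Σ_b = 0) switches to plain OLS; the singular
  marginal covariance otherwise uses a pseudoinverse.
- Cox convergence is lifelines' default Newton tolerance with the damped
  retry ladder above; Wald CIs are exp(β ± 1.96 SE).
- DeLong with zero variance (e.g., a marker compared with itself) returns
  Z = 0, p = 1; a degenerate single-marker variance yields p = 0 unless the
  AUC is exactly 0.5.
- Tie-breaks: horizon selection prefers the earlier scan; cluster counting
  uses ≤ at both erf and σ thresholds.

## Problem sizes

Tests and the acceptance script run on 6³–10³ voxel grids with 30–200
subjects, 10⁵–2.4×10⁵ voxel draws for calibration, 200 replicates of
n = 500 subjects for hazard-ratio recovery, and 500–1000 replicates for
type-I error — sizes at which every stated tolerance is comfortably
resolvable on one CPU in a few minutes.

## Known limitations

Per-voxel REML in `voxel` mode is slow beyond ~10³ voxels; the pooled mode
is the practical default. The BLME stage is insensitive to purely linear
excess decline (a subject whose loss is fast but linear matches their own
extrapolated trajectory) — an inherent property of deviation-from-own-
trajectory methods, most relevant to *C9orf72*-like progression. The
horizon analysis selects scans near the window boundary, so signal depends
on acceleration having begun by ~27 months before conversion; under the
default generator (lag 1 year) most selected scans precede onset and the
24-month AUC is accordingly modest.
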