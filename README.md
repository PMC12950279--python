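# atrophy-forecast

Individualized prediction of conversion to dementia from longitudinal
structural MRI, built for familial frontotemporal lobar degeneration
(f-FTLD) cohorts of *C9orf72*, *GRN*, and *MAPT* mutation carriers and
their non-carrier family controls. Because real consortium data of this
kind are available only by application, the package ships a first-class
synthetic cohort generator so every stage — trajectory modeling, deviation
mapping, survival analysis, and horizon classification — runs and is tested
end to end without any download.

## The method

**Voxel-wise BLME trajectory prediction.** At each voxel the normative
model is a Bayesian linear mixed-effects (BLME) model fit to control scans,

    y_ij = β₀ + β₁ t_ij + a_i + b_i t_ij + ε_ij,
    (a_i, b_i) ~ N(0, Σ_b),   ε_ij ~ N(0, σ²_ε),

with variance components estimated by REML. A carrier's first two scans
(the *predictor scan pair*, both acquired at global CDR + NACC-FTLD ≤ 0.5)
update the random-effect prior by normal–normal conjugacy, giving a
posterior over that subject's own (intercept, slope) and hence a Gaussian
posterior-predictive distribution N(μ_v(t), s_v(t)²) for each voxel at any
later time. Follow-up scans (never the pair itself) are scored with the
error function of the standardized deviation,

    erf( (y_obs − μ_v(t)) / (s_v(t) √2) )  ∈ (−1, 1),

negative where volume falls below prediction; |erf| = 0.999 corresponds to
a two-sided predictive tail probability of 0.001. Voxels with erf at or
below a negative threshold (sweep −0.7 … −0.999) are counted and multiplied
by voxel volume: the *BLME cluster volume* in mm³.

**Comparators.** Cross-sectional W-maps (per-voxel standardized residuals
from a control OLS regression on age, TIV, and scanner; σ threshold sweep
1.0 … 3.0, where σ = 3 corresponds to a one-sided normal tail of ≈ 0.00135)
and atlas ROI mean volumes (frontal/temporal composites).

**Survival.** Each metric is z-scored and entered as a time-dependent
predictor in a Cox proportional-hazards model on the counting-process
scale (Efron ties, via lifelines), with age (plus TIV for ROI metrics) as
covariates; conversion (first CDR ≥ 1) is the event, non-converters are
censored at last observation. Hazard ratios read per SD of the predictor.

**24-month horizon ROC.** One scan per subject: converters contribute
their scan closest to (and within) 27 months (24 + 3-month buffer) before
conversion; non-converters need a scan at least 24 months before last
observation. AUCs use the Mann-Whitney statistic with DeLong variance, and
DeLong's paired test compares markers.

## Worked example

```python
from atrophy_forecast import (CohortConfig, simulate_cohort, compute_metrics,
                              survival_analysis, select_horizon_subset, roc_auc)

cohort = simulate_cohort(CohortConfig(n_controls=40, n_carriers=120,
                                      grid_shape=(10, 10, 10), seed=7))
metrics = compute_metrics(cohort)           # BLME + W-map + ROI metrics

fit = survival_analysis(cohort, metrics, "blme_cluster_mm3@-0.999")
c = fit.coefficient("blme_cluster_mm3@-0.999")
print(f"HR per SD = {c.hr:.2f}, p = {c.p:.2g}, events = {fit.n_events}")

subset = select_horizon_subset(cohort, metrics)   # 24-month horizon
scores, labels = subset.scores_labels("blme_cluster_mm3@-0.999")
res = roc_auc(scores, labels)
print(f"AUC = {res.auc:.2f} (95% CI {res.ci[0]:.2f}-{res.ci[1]:.2f})")
```

prints

```
HR per SD = 1.82, p = 0.00029, events = 7
AUC = 0.59 (95% CI 0.34-0.83)
```

— under default (moderately signaled) conditions the per-SD hazard ratio of
the BLME cluster volume is ≈ 1.8 (each SD of unexpectedly-low-volume
cluster nearly doubles the instantaneous conversion risk), while the
24-month AUC is modest because most selected scans precede the simulated
acceleration onset. The same CLI pipeline is available as
`atrophy-forecast run-all --seed 7 --out out/` (see
`atrophy-forecast --help` for the per-stage subcommands `simulate`,
`deviation`, `wmap`, `roi`, `survival`, `roc`, `validate`).

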