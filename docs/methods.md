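# Methods

This note documents the statistical model behind `trialconsist`, the
defaults and their rationale, the synthetic-trial generator's scope, and
the numerical choices made in the implementation.

## Setting and model

The package targets two-endpoint multicenter randomized survival trials.
Each patient record carries a treatment arm (1 = treatment, 0 = control),
a center, a country, a remission-status stratum (CR1 / CR>1), and two
right-censored endpoints: a surrogate (leukemia-free survival, LFS: time to
relapse or death, whichever first) and a true endpoint (overall survival,
OS: time to death). By construction `lfs_time ≤ os_time` and a death is
always an LFS event.

The treatment effect is estimated by a stratified Cox proportional-hazards
model with the single binary covariate "arm": each stratum (by default
country × CR status) has its own unspecified baseline hazard, and all
strata share one log hazard ratio β. Hazard ratios are reported in the
*benefit orientation*, `hr = exp(−β)`, so HR > 1 means the treatment
reduces the event hazard; `orientation="conventional"` reports `exp(β)`.
Significance testing uses the stratified log-rank test: per stratum and
per distinct event time the observed-minus-expected event count in one arm
and its hypergeometric variance are accumulated, giving
χ² = (O − E)²/V with 1 degree of freedom. Its direction (the sign of O − E
in the control arm) matches the sign of the Cox estimate.

Strata in which no events occur, or in which all patients fall in one arm,
contribute nothing to either statistic; they are dropped and counted in the
result (`degenerate_strata_dropped`). A fit is declared non-estimable
(raising `EstimationError`) when no usable stratum remains or the partial
likelihood is monotone (all informative events point one way, |β| → ∞).

## Consistency

For S subsets with effect estimates τᵢ (log-HR scale) and standard errors
sᵢ, and the overall trial estimate τ, the heterogeneity statistic is

    X² = Σᵢ (τᵢ − τ)² / sᵢ²,

approximately chi-square with S − 1 degrees of freedom under homogeneity.
When no overall estimate is supplied the inverse-variance pooled mean of
the subsets is used, as in meta-analysis; the trial-level analyses pass the
full-data stratified Cox estimate. The inconsistency index

    I² = (X² − S + 1) / X²  if X² > S − 1, else 0

is the estimated fraction of between-subset variability beyond chance,
read as little (< 0.33), moderate (0.33–0.67) or substantial (> 0.67)
inconsistency.

A *reversal* is a subset whose estimated effect has the opposite sign to
the overall effect. For S subsets of equal size (for survival endpoints,
comparable event counts), the subset-level Wald statistic has roughly √S
times the overall standard error, so the chance of a given subset
reversing is approximately Φ(−z/√S), with z the overall benefit-oriented
Wald statistic. `z_from_summary` recovers z from a published HR and
confidence interval via se = (ln CI_hi − ln CI_lo) / (2 z_{(1+γ)/2}).

Forest tables (`build_forest`) refit the stratified Cox model inside each
level of a categorical covariate (country uses CR status only as stratum,
since country is the splitting variable). Subsets smaller than
`min_patients` (default 5) or non-estimable are excluded and reported with
a reason; splitting on `arm` itself is rejected as confounded.

## Robustness

Leave-one-center-out (LOCO) removes each center in turn and re-runs the
analysis (stratified log-rank P by default; `test="wald"` uses the Cox
Wald P). Reported per center: the refitted HR and P, patients and events
removed, and an estimability flag; the summary gives the min/mean/max P
over estimable rows and a fixed-width P-value histogram.

Sequential elimination ranks centers once on the full data — by patient
count (default) or event count, largest-first or smallest-first, ties
broken lexicographically by center id — and removes them in that fixed
order, refitting after each removal, stopping at the first step where
P > α (default 0.05), when a refit becomes non-estimable, or when only one
center would remain. The initial ranking is deliberately not recomputed
between steps so that the path is a deterministic function of the data.

## Trial-level surrogacy

Per-country stratified Cox fits (stratified by CR status only) give paired
effects (HR_surrogate, HR_true); countries below `min_patients` or with a
non-estimable fit on either endpoint are excluded. A weighted least-squares
line HR_true = a + b·HR_surrogate is fitted via `statsmodels` WLS, with
weights equal to country patient counts (default), inverse variances
(delta-method, on the HR scale), or equal; an alternative log-HR scale is
available. R² from the weighted fit measures trial-level surrogacy; the
slope's t-test P-value is reported. At least 3 countries are required.
Known limitation: no errors-in-variables correction — the regression
treats the estimated HRs as fixed, so sampling error in the per-country
estimates attenuates the slope and deflates R² in small countries.

## Synthetic-trial generator

`generate_trial` draws, per patient: arm ~ Bernoulli(allocation_ratio),
remission status ~ Bernoulli(cr1_fraction), optional categorical
covariates, and three exponential event-time components —

- time to relapse, hazard `relapse_hazard_control` multiplied by country
  and covariate modifiers and by `cr_gt1_hazard_multiplier` for CR>1
  patients;
- time to death without relapse, hazard `non_relapse_death_hazard`,
  competing with relapse from randomization;
- time from relapse to death, hazard `post_relapse_death_hazard`.

LFS is the earlier of relapse and non-relapse death; OS is death; both are
administratively censored at `followup_days`. Treatment divides **both**
LFS components by `treatment_effect_hr`, so the oriented LFS hazard ratio
equals the configured value exactly within every stratum — this makes the
planted parameter a clean estimand for recovery tests. The effect on OS is
*not* planted: it emerges mechanically from relapse prevention, diluted by
the relapse-to-death lag and by treatment-independent post-relapse
mortality, so the OS hazard ratio is attenuated toward 1 relative to the
LFS hazard ratio. An optional `direct_os_treatment_hr` knob divides the
mortality hazards directly for surrogacy stress-tests, and
`center_treatment_hr_overrides` plants center-specific effects for
robustness stress-tests.

Defaults (`default_trial_config`) encode the reference study conditions:
320 patients, 10 countries, 92 centers with sizes in [1, 17] (a documented
skewed allocation; the real center-size distribution is unknown),
1:1 allocation, CR1 fraction 261/320, oriented LFS HR 1.43, follow-up
1460 days. The default hazards — relapse 8.3 × 10⁻⁴/day, post-relapse
death 2.6 × 10⁻³/day, non-relapse death 5 × 10⁻⁵/day — were calibrated
once, by simulation, so that a default trial yields on average ≈ 236 LFS
events and ≈ 196 deaths; they were fixed before any downstream test was
written and have not been revisited. Scope limitations: exponential
components only (the Cox analyses are valid regardless of baseline shape);
covariates have independent marginal prevalences, no joint structure; no
salvage-therapy modeling.

Reproducibility: one `numpy` Generator seeded from `config.seed` fills a
row-major `(n_patients, 5 + n_covariates)` uniform matrix, so a patient's
draws depend only on their row index — enlarging a trial preserves all
earlier patients, and identical seeds give byte-identical CSVs.

## Numerical choices

- **Ties**: Efron's approximation throughout (exact for untied data and
  generally closer to the exact partial likelihood than Breslow). Note
  that duplicating every patient creates ties and therefore does *not*
  leave the Efron estimate exactly invariant; tests of duplication
  symmetry compare against an independent Efron implementation.
- **Newton–Raphson**: start β = 0, steps clamped to ±2, convergence when
  |score| < 10⁻⁸, at most 100 iterations; |β| > 15 is diagnosed as a
  monotone likelihood.
- **Confidence intervals**: Wald on the log-HR scale (default 95%).
  Two-sided P-values are clamped away from exact 0 at the smallest
  positive double.
- **Determinism**: all analyses are pure functions of (data, options);
  subset labels and tie-breaks are lexicographic; TSV/JSON outputs are
  byte-stable across runs.
- **Performance**: the Cox solver precomputes per-stratum risk-set sums,
  so a full stratified fit on a 5000-patient trial takes ~10 ms; the
  Monte-Carlo validation suites (200 × n = 5000 recovery, 500 null
  calibrations, 1000 × 7-subset reversal check) run in well under five
  minutes total.

## Validation summary

The test suite validates: the Cox solver against grid-search maximization
of a naively coded Efron partial likelihood (10⁻⁶) and against an
independent library implementation; the log-rank statistic against hand
tabulation (10⁻⁹); exact symmetries (arm relabeling inverts the HR,
identical arms give HR 1 and χ² 0); recovery of the planted LFS hazard
ratio and null calibration of the heterogeneity test by simulation; the
reversal-probability formula against empirical reversal frequencies; the
surrogacy WLS against closed-form weighted normal equations and planted
linear truths; and structural invariants of the LOCO and elimination
analyses (row counts, conservation, duplicated-center symmetry,
deterministic tie-breaking).
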