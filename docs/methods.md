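# Methods

This note documents the models implemented in `empasim`, the conditions
under which synthetic data are generated, the numerical choices behind the
estimators, and what the package's tests do and do not establish about
real trial data.

## Background and scope

Empagliflozin 10 and 25 mg improved glycemic control in two phase-III
trials in type 1 diabetes (52 and 26 weeks); a 2.5-mg dose was included in
only one of them. The package reproduces, on fully synthetic data, the
modeling-and-simulation workflow that generated supportive evidence for the
low dose: two independently specified exposure–response models are built
from the higher-dose information and then used to simulate 2.5-mg trial
scenarios. Safety endpoints (beta-hydroxybutyrate, diabetic ketoacidosis)
are out of scope, as is the full population-PK covariate model: the
exposure–response models consume only the individual steady-state exposure
AUC<sub>ss</sub>, so exposures are sampled directly (see below).

All times are hours (the published placebo slope is in %/h), HbA1c is in
percent, MDG (cumulative mean daily glucose over 24 h) in mg·day/dL, TDID
(total daily insulin dose) in IU/kg, and exposures in nmol·h/L.

## Virtual populations

Covariate distributions are quantile-matched to the published per-study
demographic summaries (median and 95% interval) — log-normal for weight,
eGFR, baseline TDID and baseline HbA1c (the published intervals are
right-skewed), zero-truncated normal for age, Bernoulli(0.5) for sex and
Bernoulli(0.36) for pump (CSII) use (64% of patients used multiple daily
injections). For a log-normal the match sets the log-location to the log
median exactly and the log-scale to `log(q_high/q_low)/(2·1.96)`, the
least-squares compromise between the two tails; the implied tail quantiles
land within ~3.5% of the published ones where the published interval is
asymmetric on the log scale.

Baseline MDG is not part of the published demographics; it is log-normal
around the reference value 4266 mg·day/dL with a 15% CV, a typical spread
for a glycemic summary of this kind (config-exposed).

Visit schedules are not printed. HbA1c/MDG visits are weeks
0, 4, 12, 26, 39, 52 truncated to the study duration, and TDID is recorded
daily; this reproduces the reported per-endpoint observation counts to
within 10% for HbA1c (4326 generated vs. 4750 reported for the 52-week
study; 150 vs. 149 for the 4-week study). Arms are allocated in equal
proportions.

Exposures: the full population-PK model is replaced by direct log-normal
sampling of AUC<sub>ss</sub> with dose-proportional median calibrated so
the 2.5-mg typical value is 498 nmol·h/L (the reported low-dose exposures
are centered at the estimated AUC50) and a 35% CV, typical between-patient
PK variability for a small molecule without strong covariate effects. The
two-compartment concentration model (sequential zero/first-order
absorption with lag) is provided for completeness and is verified against
the closed form AUC = dose/CL; all exposure–response code uses the closed
form.

## Descriptive Bayesian Emax model

Structural model, per patient *i* and visit *j*:

```
HbA1c_ij = B_i − E_i · AUC_i/(AUC50 + AUC_i) + θ_d · c_i · t_ij + ε_ij
B_i = θ_a · exp(η_z,i),   E_i = θ_c · h_i · exp(η_s,i)
```

with additive Gaussian residual ε (SD σ, default 0.25%), log-normal random
effects η, and the covariate factor
`h_i = (HbA1c0_i/8.1)^p1 · (eGFR_i/98)^p2`. The only covariate
coefficients with recoverable published values are back-solved from the
reported relative effects: `p1 = log(1.32)/log(9.5/7.2) ≈ 1.00` (a 32%
Emax increase over the observed baseline range), `p2 = log(1.50)/
log(120/54) ≈ 0.51`, and a 1.47 multiplier on the placebo slope for CSII
patients. All other covariate coefficients are null. The additive
(percentage-point) Emax form is primary; a proportional variant exists
behind a flag for comparison only. The drug term is a direct
(steady-state) effect — time-invariant after the first on-treatment
visit — because the endpoint schedule cannot identify indirect-response
dynamics; the baseline visit carries no drug term.

Reference estimates: baseline 8.14%, AUC50 498 nmol·h/L, Emax 0.579%,
placebo slope 2.61e-5 %/h.

### Priors

AUC50 carries an informative log-normal prior with location 704 nmol·h/L
(from a type-2-diabetes exposure–response analysis of FPG/HbA1c). Its
variance is not published; the default is log-SD 0.25, a level of
informativeness consistent with the reported observation that the final
model's simulated distribution falls close to the one obtained with AUC50
fixed to the prior value. The sensitivity grid (below) sweeps this choice.
Remaining fixed effects get wide normal priors; the two variance
components get weakly-informative normal priors on the log-SD scale (the
covariance structure here is diagonal with two scalar elements, so an
inverse-Wishart adds nothing over this simpler, better-behaved choice);
σ gets a weak log-normal prior.

### Estimation: marginalized likelihood + NUTS

The posterior is sampled with a No-U-Turn sampler (multinomial HMC with
dual-averaging step-size adaptation toward 0.8 acceptance and a diagonal
mass matrix estimated from the middle warm-up window), implemented in
`empasim.mcmc`. Four chains with independently jittered initial values,
500 warm-up + 1000 kept draws by default; R̂ and effective sample sizes
are computed via arviz and divergences are surfaced, never swallowed.

Rather than sampling ~1600 patient-level random effects, the sampler
targets the marginal likelihood obtained by moment-matching each
log-normal random effect to a Gaussian: per patient the observation vector
is Gaussian with mean
`E[B_i] − E[E_i]·w_i·1{t>0} + θ_d c_i t` and covariance
`Var[B_i]·11' + Var[E_i]·w_i² m m' + σ² I` (rank-2 plus diagonal; `w_i`
is the saturating exposure weight). The Woodbury identity reduces every
required quantity to per-patient scalar sufficient statistics, and the
gradient is analytic (verified against finite differences and against a
dense linear-algebra construction in the test suite). The moment match is
exact in the first two moments and very accurate at the variability levels
of interest (log-SDs ≤ 0.3); the joint density with explicit random
effects is also implemented (`log_density`) and used for the exactness
tests. One full 4-chain fit of ~800 patients takes ~15 s.

Parameter scales: the sampler works in log coordinates for all positive
parameters and scales the placebo slope by 1e4 so all coordinates are
O(1) before mass adaptation.

### Prior sensitivity

The sweep refits the model with the prior variance fixed to zero, at the
default, inflated 10-, 50- and 100-fold, and essentially flat, and with
the location moved to 22,026, 0.00005, +50% and −50% of 704. Expected
(and tested) behavior: zero variance pins the posterior AUC50 to the
location exactly; widening the prior lets the posterior AUC50 fall toward
the likelihood and therefore increases the predicted drug effect;
raising the location decreases it.

## Semi-mechanistic chain

Three direct-effect submodels estimated stepwise, mirroring how the
original analysis decomposed the problem:

1. **Insulin.** `TDID_ij = TDID0_i · Inc · (1 − Emax_T·AUC/(AUC50_T+AUC))`
   — nonlinear least squares on the log ratio to the observed individual
   baseline (Emax_T on the logit scale, AUC50_T on the log scale). The
   amplitude factor `Inc` applies only to week 1 of the 4-week phase-II
   study and is estimated only when such records exist (its value is
   unpublished; the generator default is 1.15). Placebo-only data leave
   the drug effect unidentifiable and are flagged, not silently fitted.
2. **Glucose.** The linear placebo drift is regressed from placebo MDG
   records; `γ` (insulin-effect power), Emax_M and AUC50_M are then fitted
   to active-arm records with proportional residuals and step-1 parameters
   fixed. Under the synthetic generator the placebo insulin ratio is
   exactly 1, so γ carries no information in placebo data and is
   identified from the active arms (where the two different AUC50s of the
   insulin and glucose terms separate the pathways).
3. **HbA1c.** `log HbA1c = log HbA1c0 + wt·log(WT/82) + log(sexmult)·F +
   θ_b · log(MDG ratio) + b_i + ε`, a linear mixed model (random intercept
   per patient, statsmodels) on the individual MDG profiles derived from
   step 2.

Reference estimates: Emax_T 0.186, AUC50_T 110, Emax_M 634 mg·day/dL,
AUC50_M 370, γ 0.487, baseline 8.15%, weight power −0.0258, female
multiplier 0.99.

θ<sub>b</sub> (MDG→HbA1c power) and the placebo MDG slope are not
published. The slope defaults to a small positive drift
(0.01 (mg·day/dL)/h, ~1% of baseline by week 26; placebo-adjusted
contrasts cancel it to first order). θ<sub>b</sub> is calibrated by 1-D
root finding so the typical-value week-26 placebo-adjusted change at 10 mg
equals the reported −0.44%; this gives θ_b ≈ 0.231 and implies −0.48 at
25 mg (reported −0.50) and −0.32 at 2.5 mg (reported −0.29 to −0.31).

A known directional caveat: as printed, insulin down-titration (ratio < 1
with γ > 0) *lowers* MDG, so switching the insulin effect off ("stable
insulin") yields a *smaller* HbA1c decrease — the opposite ordering of the
published stable-vs-adjusted comparison. The equation is implemented as
printed; `flip_gamma_sign` exposes the alternative convention, under which
the published ordering (stable ≈ 30% greater decrease) is reproduced
qualitatively. The 2.5-mg adjusted-insulin prediction, the package's
headline use of this model, is unaffected by the convention.

## Trial simulation

A scenario draws, per replicate, one parameter vector from the chosen
uncertainty source, resamples patients from the virtual population,
simulates each sampled patient under active treatment and under placebo
(fresh exposures and residuals), and records the median placebo-adjusted
change from baseline. Two published sampling rules are implemented: 239
patients without replacement per replicate for the descriptive-model
2.5-mg prediction, and 500 patients per dose group from the pooled study
populations for the insulin-regimen scenario. 500 replicates by default.

Parameter uncertainty: posterior draws for the descriptive model, or
independent log-normal draws calibrated to the published 95% CIs
(log-SD = `log(hi/lo)/3.92`) when a fit is not in play; the
semi-mechanistic chain uses the CI-calibrated draws (the published table
provides no covariance), with draws violating `Emax_T < 1` rejected,
redrawn and counted. Replicate summaries use the median (means available
behind a flag); thresholds −0.20% and −0.25% follow the published
reporting.

## Diagnostics

VPCs bin by nominal visit time and compare observed percentiles
(2.5/50/97.5) against the across-replicate band of the same simulated
percentiles; landmark checks reuse the same machinery at one visit.
Percentile convention: linear interpolation between order statistics
(numpy default), fixed package-wide. The nonparametric bootstrap resamples
whole patients (all rows of an ID move together, preserving longitudinal
dependence), reports percentile CIs, and counts failed refits.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the models assume:
quantile-matched covariates, log-normal exposures, direct-effect drug
terms, linear placebo drift, additive/proportional residuals. It does not
emulate dropout, adherence, insulin-titration dynamics beyond the model
equations, assay drift, or visit-window jitter. Passing recovery tests
therefore demonstrate correctness of the estimators under the models' own
assumptions — not robustness to the misspecifications real trial data
would add. Two consequences observed in the package's own experiments are
documented here deliberately: (i) with data only at the effect plateau
(10/25 mg), AUC50 is weakly identified and its posterior median shifts
toward the prior location; (ii) the replicate-threshold fractions carry
~2-percentage-point binomial noise at 500 replicates.

## Numerical choices and problem sizes

Residual defaults: HbA1c additive SD 0.25%, MDG proportional CV 5%, TDID
proportional CV 3% (magnitudes unpublished; all config-exposed). Random
effects: Emax log-SD 0.25; baseline variability enters through the sampled
baseline covariate (log-SD ≈ 0.07 for the 52-week-study interval).
Root-finding for θ_b uses Brent's method on (0, 5) with 1e-12 tolerance.
Least-squares fits use Levenberg–Marquardt with analytic-free Jacobians;
convergence flags and messages are preserved on every fit object.
Divergent NUTS transitions are defined by an energy error > 1000; a
post-warm-up divergence rate above 5% raises a warning.

Default problem sizes (tests and the acceptance script use these): 721-
and 75-patient populations for the 52- and 4-week designs, 500-replicate
scenarios, 4 chains × (500 + 1000) NUTS draws for headline fits and
2 chains × (250–400 + 300–600) for the sensitivity sweep and property
tests; these sizes keep a full end-to-end reproduction to a few minutes on
one CPU while leaving Monte Carlo error well inside the published
reporting precision (except the threshold-fraction noise noted above).

## Known limitations

* The marginal likelihood linearizes the random effects via moment
  matching; at log-SDs far above 0.3 the approximation would degrade.
* Covariate coefficients other than the three recoverable from published
  relative effects are fixed at null, and the three recoverable ones are
  treated as known constants during refitting.
* The stepwise chain conditions on observed baselines rather than
  estimating latent ones; this is exact for the synthetic generator but
  would understate uncertainty on noisy real baselines.
* The stable-vs-adjusted insulin ordering depends on the sign convention
  discussed above and is only qualitatively reproduced.
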