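# empasim

Exposure–response modeling and clinical-trial simulation for a low
(2.5 mg) dose of the SGLT2 inhibitor empagliflozin as adjunct to insulin
in type 1 diabetes.

Large phase-III evidence for empagliflozin in T1D exists for the 10- and
25-mg doses; the 2.5-mg dose — attractive because the diabetic-ketoacidosis
risk rises with dose — was studied in only one trial. `empasim` implements
the model-informed approach to generating supportive evidence for the low
dose: build exposure–response models on the higher-dose data, then simulate
untested 2.5-mg trial scenarios. It is aimed at pharmacometricians and
biostatisticians who want a transparent, fully synthetic, end-to-end
re-implementation of that workflow.

## Models

Two independent frameworks predict the placebo-adjusted HbA1c change from
baseline as a function of the individual steady-state exposure
AUC<sub>ss</sub> (nmol·h/L):

**Descriptive Bayesian Emax model** (`empasim.mease2`) — for patient *i*
at time *t* (hours):

    HbA1c_ij = B_i − E_i · AUC_ss,i / (AUC50 + AUC_ss,i) + θ_d · c_i · t

with log-normal inter-individual variability on the baseline `B_i` and the
maximal effect `E_i`, covariate powers on Emax (baseline HbA1c, eGFR), a
CSII multiplier `c_i` on the linear placebo drift, and an informative
log-normal prior on AUC50 (location 704 nmol·h/L, carried over from a
type-2-diabetes analysis). The posterior is sampled with an in-package
No-U-Turn sampler on an analytically marginalized likelihood.

**Semi-mechanistic chain** (`empasim.mease1`) — insulin → glucose → HbA1c:

    TDID/TDID0 = Inc · (1 − Emax_T · AUC/(AUC50_T + AUC))
    MDG        = MDG0 · (TDID/TDID0)^γ + PBO·t − Emax_M · AUC/(AUC50_M + AUC)
    HbA1c      = HbA1c0 · (MDG/MDG0)^θ_b · exp(η)

estimated stepwise (insulin first, then glucose with insulin fixed, then
HbA1c on the derived glucose profiles). The unreported MDG→HbA1c power
θ<sub>b</sub> is calibrated so the typical 10-mg week-26 effect matches the
reported −0.44%.

Around the models: quantile-matched virtual trial populations
(`empasim.population`), dose-proportional exposure sampling
(`empasim.exposure`), replicated trial simulation with parameter
uncertainty and a prior-sensitivity grid (`empasim.trial_sim`), and
VPC/landmark/R̂/ESS/bootstrap diagnostics (`empasim.diagnostics`).

## Worked example

Simulate the headline scenario — 500 replicated trials, each drawing 239
patients without replacement from a virtual 52-week-study population, a
2.5-mg arm versus placebo, parameter uncertainty calibrated to the
published 95% intervals:

```python
from empasim import mease2, population, trial_sim

pats = population.sample_population(
    population.StudyDesign.from_reference("EASE2"), seed=11)
active = pats[pats["arm"] > 0].reset_index(drop=True)

spec = trial_sim.ScenarioSpec(model="MEASE2", n_replicates=500, n_patients=239)
summ = trial_sim.run_scenario(spec, active, mease2.MEase2Params(), seed=12)
print(trial_sim.grand_summary(summ).round(3).to_string(index=False))
```

```
 arm  week  grand_median   q2.5  q97.5  frac_le_0.20  frac_le_0.25
 2.5    26        -0.297 -0.428 -0.189         0.952          0.81
```

Read: the median simulated trial shows a placebo-adjusted HbA1c reduction
of 0.30 percentage points at week 26 for 2.5 mg once daily; 95% of the
replicate medians reach at least a 0.20-point reduction and 81% reach
0.25 — i.e., a clinically relevant low-dose effect is predicted in nearly
every simulated trial.

The same workflow is scriptable from the shell:

```sh
empasim generate-data --study EASE2 --out data
empasim simulate-scenario --replicates 500 --out summaries.csv
empasim run --out runs/full          # full pipeline + digest.json
```

## Documentation

`docs/methods.md` describes the models, their assumptions, the synthetic
data-generating conditions, numerical choices and known limitations.
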