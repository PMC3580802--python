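# ebdose

Empirical-Bayes drug dosage individualization built on a random-intercept
log-linear model of steady-state pharmacokinetic/pharmacodynamic response.

The model for a patient's trough steady-state response `Y` at dose `D` is

```
log Y = alpha + beta' x + d * log D + eps
```

where `alpha` is a patient-specific intercept (normal across the population
with mean `mu_alpha`, variance `sigma_alpha2`), `x` are patient covariates
with fixed effects `beta`, `d` is the dose exponent (1 under linear
kinetics), and `eps` is intra-patient log-normal noise with variance
`sigma_eps2`.

The package provides:

- **`ebdose.core_model`** — long-format data handling, ML/REML fitting of the
  model (fixed effects profiled analytically, variance ratio optimized on a
  log scale, between-patient variance floored at zero), per-patient
  log-residuals, JSON model serialization.
- **`ebdose.empirical_bayes`** — closed-form BLUP/empirical-Bayes posterior of
  a patient's intercept from accumulated (dose, response) pairs, and the
  standardized `gamma` index `(alpha - mu_alpha)/sigma_alpha`.
- **`ebdose.dosing`** — the dosing algorithm: initial dose for the average
  patient, empirical-Bayes dose updates targeting the geometric midpoint of a
  therapeutic window `(l1, l2)`, window probabilities (Bayes risk), the
  maximum attainable window probability, omega-optimality, the traditional
  proportional TDM adjustment, and a Monte-Carlo estimate of the minimum
  number of blood samples needed for an omega-optimum dose.
- **`ebdose.effects`** — relative-percentile effect sizes
  `E = (exp(b) - 1) x 100%`, dose-correction factors `exp(-b)`,
  stratum-specific (interaction) effects, and the three-condition
  variance-decomposition screen for candidate genetic covariates.
- **`ebdose.simulate`** — synthetic populations with known ground truth and a
  common-random-numbers trial engine comparing dosing strategies
  (empirical Bayes vs. traditional TDM vs. a fixed population dose).

## CLI

```sh
# fit a model to long-format CSV (patient_id,dose,response,<covariates...>)
ebdose fit data.csv -o model.json --method REML

# recommend the next dose for a patient (history CSV: dose,response)
ebdose dose --model model.json --l1 2 --l2 6 -x 1 --history history.csv

# per-covariate effect sizes and dose-correction factors
ebdose effectsize --model model.json

# head-to-head strategy simulation from a YAML config
ebdose simulate scenario.yaml -o summary.csv --trajectories traj.csv

# three-condition screen of a candidate covariate column
ebdose screen data.csv --base smoker,sex --variant rs123 --n-boot 500 --seed 1
```

A simulation config looks like:

```yaml
population: {mu_alpha: 1.0, sigma_alpha2: 0.09, sigma_eps2: 0.04,
             beta: [0.3], d: 1.0, covariate_names: [smoker]}
covariates: [{name: smoker, dist: binary, p: 0.5}]
window: {l1: 2.0, l2: 6.0}
omega: 0.9
n_patients: 2000
n_steps: 6
strategies: [empirical_bayes, tdm]
seed: 42
```

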