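# lznpk

Population pharmacokinetics and toxicodynamics of linezolid in critically
ill patients: model estimation, individual exposure, toxicity thresholds
and Monte Carlo dose optimisation.

Linezolid is dosed at a fixed 600 mg q12h despite large between-subject
variability in exposure and a clear exposure–toxicity relationship for
myelosuppression (thrombocytopenia and/or anemia). This package implements
the full analysis a clinical pharmacology group would run to individualise
dosing from sparse therapeutic-drug-monitoring data:

1. **Population PK.** A one-compartment IV-infusion model with linear
   elimination, fitted by first-order conditional estimation with
   interaction (FOCE-I). Clearance carries the renal covariate:

       CL (L/h) = θ₁ + θ₂ · (CrCL / 65),   V (L) fixed effect,
       CLᵢ = CL · exp(ηᵢ),  ηᵢ ~ N(0, ω²),   y = f · (1 + ε),  ε ~ N(0, σ²)

   with CrCL the Cockcroft–Gault creatinine clearance. Stepwise covariate
   selection (forward ΔOFV ≥ 3.84, backward ΔOFV ≥ 6.63), nonparametric
   bootstrap, CWRES, shrinkage and a prediction- and variability-corrected
   VPC are provided as diagnostics.
2. **MAP Bayes.** Individual clearance by maximum-a-posteriori estimation
   under the population prior; steady-state trough (closed form) and
   AUC₀₋₂₄ (linear-up/log-down trapezoid on a 10-min grid).
3. **Toxicodynamics.** Logistic regression of myelosuppression on the
   steady-state trough, P(tox) = 1/(1 + exp(b₀ − b₁·Cmin)); the trough at
   50% risk is the toxicity ceiling. The efficacy floor comes from
   inverting the near-deterministic Cmin–AUC regression at the
   AUC₀₋₂₄/MIC ≥ 80 target. Kaplan–Meier time-to-toxicity included.
4. **Dose optimisation.** Monte Carlo probability of target attainment
   (PTA) of the trough window across renal-function strata
   (<30, 30–59, 60–89, ≥90 mL/min) for 300–600 mg given q8h/q12h/q24h.

A synthetic-cohort generator reproduces the study conditions (83 ICU
patients, ~127 sparse trough-dominant samples, 600 mg q12h 1-h infusions,
toxicity outcomes from the logistic model) so the whole pipeline is
testable without patient data.

## Worked example

```python
import lznpk as L

cohort = L.generate_cohort(L.CohortConfig(seed=1)).fit_subset()
fit = L.foce_fit(cohort)
print(fit.report_text())
```

```
Parameter                 Estimate   RSE (%)
--------------------------------------------
theta_cl_intercept           3.332        --
theta_crcl_on_cl             2.411        --
volume                       51.46        --
omega_cl                    0.3632        --
sigma_prop                   0.183        --
--------------------------------------------
OFV 546.466   AIC 556.466   BIC 570.527
eta-shrinkage 5.5%   eps-shrinkage 38.2%
converged: True
```

The refit recovers the generating values (θ₁ = 3.66 L/h, θ₂ = 2.18 L/h,
V = 54 L, ω = 0.352, σ = 0.19) within sampling error of an 83-subject,
sparse-sampling design. The therapeutic trough window follows from the
toxicodynamic models:

```python
window = L.therapeutic_window(L.ExposureRegression(),
                              L.EfficacyTargetConfig(), L.LogisticTD())
# TherapeuticWindow(lower=2.6, upper=7.8)   # mg/L
```

2.6 mg/L is the trough whose regression-implied AUC₀₋₂₄ reaches the
160 mg·h/L efficacy requirement (AUC/MIC ≥ 80 at MIC 2 mg/L); 7.8 mg/L is
the trough at 50% myelosuppression probability. PTA across renal strata
then ranks candidate regimens:

```python
table = L.pta_table(fit.model, window, n_per_stratum=3000, seed=1)
print(table[table["best"]])
```

```
stratum     regimen       pta  fraction_sub  fraction_supra
    <30 300 mg q12h 66.866667     24.766667        8.366667
  30-59  300 mg q8h 69.766667      9.700000       20.533333
  60-89  300 mg q8h 67.500000     23.766667        8.733333
   >=90  600 mg q8h 60.266667     21.400000       18.333333
```

Each row is the best regimen in its stratum: the percentage of simulated
subjects whose steady-state trough falls inside the window, below it
(efficacy risk) and above it (toxicity risk). Lower renal function shifts
attainment toward supratherapeutic troughs, which is what motivates dose
reduction in renal impairment.

A thin CLI wraps the same functions:

```sh
lznpk generate --n 83 --seed 1 --out pk.csv --outcomes oc.csv
lznpk fit pk.csv --json fit.json
lznpk map pk.csv --out exposures.csv
lznpk pta --lower 2.6 --upper 7.8 --n 1000 --seed 1 --out pta.csv
```

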