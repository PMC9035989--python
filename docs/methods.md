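# Methods

## Structural and statistical model

Linezolid disposition is described by a one-compartment model with
zero-order (constant-rate) infusion input and first-order elimination.
The concentration at time *t* after the start of an infusion of rate *R₀*
and duration *T* is, in closed form,

    C(t) = (R₀/CL)(1 − e^{−kt})                    t ≤ T
    C(t) = (R₀/CL)(1 − e^{−kT}) e^{−k(t−T)}        t > T,   k = CL/V

and multiple doses superpose. No ODE solver is used anywhere; the
single-dose solution is validated in the tests against high-accuracy
numerical integration.

Typical clearance is affine in creatinine clearance normalised to the
cohort-typical 65 mL/min: `CL = θ₁ + θ₂·(CrCL/65)` (defaults θ₁ = 3.66
L/h, θ₂ = 2.18 L/h). The volume of distribution (default 54 L) carries no
random effect: sparse trough-dominant sampling gives almost no individual
information on V, so its between-subject variability is fixed to zero.
Between-subject variability on CL is log-normal (`CLᵢ = CL·e^{ηᵢ}`,
ω = 0.3519, i.e. 36.3 %CV via `%CV = 100·√(e^{ω²}−1)`), and residual
error is proportional (σ = 0.1905). Creatinine clearance uses
Cockcroft–Gault with serum creatinine in µmol/L (divided by 88.4 to
mg/dL) and the 0.85 female factor.

## Estimation (FOCE-I)

The marginal likelihood is approximated by first-order conditional
estimation with interaction. Per subject, the conditional mode η̂
minimises

    Σⱼ [ (yⱼ−fⱼ)²/(σ²fⱼ²) + ln(σ²fⱼ²) ] + η²/ω²,

found by golden-section search on η ∈ [−5ω, 5ω] (the objective is
unimodal in practice; the bracket shrinks to ~3·10⁻⁸ of its span). The
subject's −2·log-likelihood contribution is then

    ln|Vᵢ| + rᵢᵀVᵢ⁻¹rᵢ + nᵢ ln 2π,
    Vᵢ = diag(σ²f(η̂)²) + ω² g gᵀ,   rᵢ = y − f(η̂) + g η̂,  g = ∂f/∂η|η̂.

Because the model has a single random effect, Vᵢ is diagonal-plus-rank-1
and every subject reduces to scalar bincount algebra; the whole cohort
objective is evaluated in a handful of vectorised array operations. The
`nᵢ ln 2π` constants are retained, making the OFV directly comparable to
an exact marginal −2LL; the tests verify agreement within 2 units against
adaptive quadrature on a small dataset.

Parameters are estimated on the log scale (hence positive). The outer
problem is solved by Nelder–Mead followed by Powell restarts from the
terminal point until the OFV changes by <0.01: Nelder–Mead alone can
contract prematurely on the flat θ₁/θ₂ ridge that sparse designs create,
and Powell's line searches traverse it. Convergence tolerances are 10⁻⁴
(relative) on the OFV and 10⁻³ on log-parameters. One restart from
perturbed initials is attempted if the optimizer reports failure. Relative
standard errors, when requested, come from the sandwich estimator
(numerical per-subject score outer products between a numerical Hessian
inverse); on the log scale the SE of ln θ is directly the relative SE.

AIC = OFV + 2p and BIC = OFV + p·ln(n_obs) with p the number of estimated
parameters. η-shrinkage is `100·(1 − SD(η̂)/ω)` and ε-shrinkage
`100·(1 − SD(IWRES))`.

Stepwise covariate selection on CL uses linear terms in covariate/ref:
forward inclusion requires an OFV drop ≥ 3.84 (χ², p < 0.05, 1 df; ties
resolved in candidate order), backward elimination removes any covariate
whose removal raises the OFV by < 6.63 (p < 0.01). Candidate pairs with
|r| > 0.95 are rejected as collinear rather than fitted.

## MAP Bayes and exposure

Individual η̂ minimises the same conditional objective under the
population prior (bounded scalar search, tolerance 10⁻⁶). Note a
consequence of the interaction term ln(σ²f²): its η-derivative is
non-zero, so even an observation lying exactly on the typical prediction
yields a small non-zero mode (O(σ²) ≈ 0.02 at σ = 0.19). This is the
correct behaviour of a conditional-mode estimator with
variance-parameter interaction; the tests assert the exact-zero property
in the σ → 0 limit.

Steady-state trough uses the closed-form intermittent-infusion
expression; AUC₀₋₂₄ uses the linear-up/log-down trapezoid on a 10-minute
grid over a 24-h window at steady state (≥10 doses and ≥7 half-lives of
prior dosing, whichever is longer). Descending segments with positive
endpoints integrate as `(C₁−C₂)Δt/ln(C₁/C₂)`; ascending, flat or
zero-touching segments fall back to the linear rule. The grid AUC agrees
with the clearance identity (daily dose/CL) within 0.5%. The trough used
downstream in the toxicity analyses is the model-derived steady-state
trough on the subject's maintained regimen, not the raw TDM sample; the
infusion duration defaults to 1 h and is configurable.

## Toxicodynamics

Myelosuppression is thrombocytopenia (platelet nadir <125×10⁹/L **and**
≥25% below baseline) and/or anemia (hemoglobin ≥25% below baseline),
boundaries read literally (≥ inclusive, < strict). Risk is modelled as
`P = 1/(1 + exp(b₀ − b₁·Cmin))` (defaults b₀ = 3.767, b₁ = 0.481),
fitted by plain maximum likelihood (statsmodels Logit); separation or a
single outcome class raises an error instead of silently diverging. The
toxicity threshold at probability p is `(logit(p)+b₀)/b₁`, reported to
one decimal (7.83 → 7.8 mg/L at p = 0.5) with full precision available.
The efficacy floor inverts the OLS Cmin–AUC line (defaults
AUC = 26.354·Cmin + 91.607) at the AUC target 80×MIC (160 mg·h/L at MIC
2 mg/L), giving 2.6 mg/L; the AUC implied at the rounded 7.8 mg/L
ceiling is 297.2 mg·h/L. Time to myelosuppression uses the Kaplan–Meier
product-limit estimator (lifelines), median defined as the first time
S(t) ≤ 0.5.

## Diagnostics

CWRES whitens the FOCE-linearised residual with the Cholesky factor of
Vᵢ. The bootstrap resamples subjects with replacement to the original
cohort size, refits each replicate warm-started at the point estimates,
and reports per-parameter medians, 2.5/97.5 percentiles and bias;
non-converged replicates are excluded and counted. The pvcVPC simulates
the fitted model at the observed design, bins observations by quantiles
of time-after-last-dose (default 6 bins; duplicate quantile edges merge
bins), rescales both observations and simulations within each bin by the
bin-median population prediction (prediction correction) and by the
bin-median simulated SD at each design point (variability correction),
then compares observed 5th/50th/95th percentiles with their simulated
90% confidence bands. Seeds: every stochastic routine takes an explicit
seed; the generator expands one master seed into independent streams.

## Synthetic cohort

The generator emulates the study conditions: 83 patients; age
N(60.6, 14.6²) in [16, 99]; 65% male; weight N(64.1, 11.2²) in
[40, 110] kg; serum creatinine log-normal (median 81 µmol/L, log-SD
0.55) in [33, 687]; CrCL recomputed from the sampled covariates via
Cockcroft–Gault and constrained by rejection to the observed
[9.99, 195.6] mL/min (median ≈ 65). Everyone receives 600 mg q12h as 1-h
infusions for a log-normal duration (median 8 days in [4, 58]). Sampling
is opportunistic: one or two samples per patient (mean ≈ 127/83), 80%
troughs (just before a dose) and the rest end-of-infusion peaks, jittered
by up to 15 min, all at steady state (≥72 h). Measurements carry
proportional error and are left-censored at the 0.1 mg/L LLOQ (censored
values are kept but excluded from fitting). Outcomes are Bernoulli draws
from the logistic risk at each subject's true steady-state trough; cases
split 20:10:4 into thrombocytopenia-only/both/anemia-only; event days are
Weibull (shape 1.8, scale 11 days) truncated at the end of therapy;
non-cases are administratively censored at the end of therapy. Hematology
baselines follow the cohort medians (platelets 232×10⁹/L, hemoglobin
99 g/L) with nadir drops drawn inside or outside the diagnostic rules so
classification reproduces the drawn labels exactly.

What the generator does **not** emulate: real TDM irregularity (dose
holds, changing regimens), covariate correlation beyond what
Cockcroft–Gault induces, time-varying renal function, concomitant
medications, and informative sampling (sicker patients sampled more).
Passing recovery tests therefore shows the estimator is correct under
the stated design, not that the design is immune to those features.

A known internal inconsistency of the published inputs, reproduced
faithfully rather than patched: simulating with the default PK model and
logistic risk under 600 mg q12h yields a myelosuppression incidence of
roughly 25–28%, lower than the 41% the source cohort reported, and the
cohort-level Kaplan–Meier median (≈12 days) is correspondingly not
reached. The generator's event rate is therefore validated for
self-consistency (empirical rate vs. the generating model's own mean
probability), not against the reported incidence. Similarly, published
per-regimen attainment percentages cannot be reconciled with the printed
model parameters under any documented assumption set, so PTA is validated
against an exact log-normal oracle (at fixed CrCL the trough is monotone
in CL, making attainment a difference of normal CDFs) and by dose
monotonicity, not against those percentages.

## Monte Carlo dosing

Virtual subjects draw CrCL uniformly within each renal stratum (the
open-ended strata truncated at the observed extremes 10 and 195 mL/min)
— the original covariate sets are unavailable, and a resampling sampler
is provided for users with their own cohort. Clearance applies the
log-normal random effect; assay error is excluded from simulated troughs
(PTA targets true individual exposure; a switch is not needed because
compute_pta accepts any subject list). The regimen grid is
{300, 450, 600 mg} × {q8h, q12h, q24h}; attainment above 80% flags an
adequate regimen.

## Problem sizes

Defaults used in the test suite: 83-subject cohorts; 10 generator seeds
for recovery medians; 200 bootstrap replicates; 1,000 VPC simulation
replicates; 10⁵ subjects for PTA-vs-oracle comparisons and 1,000–3,000
per stratum for PTA tables. These sizes give Monte Carlo error well
inside the asserted tolerances.
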