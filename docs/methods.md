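# Methods

## The model

`mtsim` implements a semi-mechanistic population PK/PD model of oral
6-mercaptopurine (6MP) maintenance therapy in childhood acute lymphoblastic
leukemia, with the absolute neutrophil count (ANC) as the observed output.

**Pharmacokinetics.** Oral 6MP is modelled as a linear three-compartment
cascade: an amount `x_6mpgut` (mg) in the gut, absorbed with rate
`k_a = 31.2/day` into plasma 6MP `x_6mp` (mg), eliminated with
`k_20 = 12.72/day`; a fraction `FM3 = 0.019` of the metabolic rate
`k_me = 9.9216/day` feeds the active metabolite pool `x_6tgn`
(6-thioguanine nucleotides), which is cleared with the body-surface-area
dependent rate `CL(BSA) = 0.219 · BSA^1.16` per day (0.00914 per hour).
Each oral dose enters as an instantaneous bolus of `F·dose` with
bioavailability `F = 0.22`. These constants are fixed literature values,
not estimated. The third equation is implemented exactly as published,
with the clearance acting as a first-order rate on the 6-TGN state and no
separate distribution volume; the 6-TGN state therefore lives on the
printed mg/L scale and the PD `slope` absorbs the scale.

**Pharmacodynamics.** Neutrophil production follows a transit-compartment
(Friberg-type) chain: proliferating cells `x_pr`, three transit
compartments, and circulating cells `x_ma` (the ANC, G/L), all coupled by a
common rate `k_tr`, with mature-cell death `k_ma = 2.3765/day`.
Proliferation is `k_tr · x_pr · (1 − E_drug) · (Base/x_ma)^γ`: the power
feedback mimics G-CSF regulation, and the drug effect is linear in the
metabolite, `E_drug = slope · x_6tgn`. `E_drug ≥ 1` (net kill) is allowed
and not clipped. The mean maturation time is `3/k_tr` (three transit
compartments): 20.3 days at the population estimate `k_tr = 0.148/day` —
biologically implausibly long, a known limitation of this model family
inherited here deliberately.

Four parameters are individual: `Base` (G/L), `k_tr` (1/day), `γ` (–),
`slope` (1/(mg/L)); each is log-normally distributed across patients,
`θ_i = θ·exp(η_i)`, `η ~ N(0, diag(ω²))`. Observations follow a
proportional error model `y = x_ma·(1+ε)`, `ε ~ N(0, σ²)`; `σ² = 0.226` is
treated as a variance (the ~48% CV interpretation; a switch to read it as
an SD exists because the published scale is ambiguous).

## Numerics

The PK cascade is linear with constant coefficients, so between events it
is advanced **exactly** by its closed-form (Bateman) solution; single-bolus
trajectories match the closed form to better than 1e-6 relative and dose
linearity holds to ~1e-12. Only the five PD states are integrated
numerically, with a classical fixed-step RK4 whose steps are aligned to
dose and observation times; since all fast rates (31.2, 12.72/day) live in
the exact part, the numerical subsystem has rates below 2.4/day and is
non-stiff. The default step is 0.05 day for plain simulation and 0.25–0.5
day during likelihood evaluation (ANC error ~5e-4 relative at 0.25 day,
small against the 48% observation CV). Trajectories reject (rather than
clamp) any step that would drive `x_ma ≤ 0`, keeping the feedback term
defined; an integration failure surfaces as an infinite objective so
optimizers retreat. A piecewise scipy LSODA integration of the same
right-hand side, restarted at each dose event, is kept as an independent
cross-check in the test suite.

During estimation, forward sensitivity equations for all five PD states
with respect to (Base, k_tr, γ, slope) are integrated with the same RK4
stages. Because the sensitivity stages are the exact derivatives of the
state stages, the resulting gradient is the machine-accurate derivative of
the *discretized* trajectory — the objective seen by the optimizer is
smooth and reproducible to ~1e-10, which finite-difference outer gradients
require.

## Estimation (FOCE with interaction)

For each patient the random-effect vector is set to its posterior mode
(empirical Bayes estimate) by BFGS on the analytic gradient of the MAP
objective

    l_i(η) = Σ_j [ (y_ij − f_ij)²/R_ij + ln R_ij ] + ηᵀΩ⁻¹η + constants,

with `R = σ²f²` (proportional) or `R = σ²` (additive). The marginal
−2 log-likelihood is then approximated by a Laplace-type expansion around
η*, with the Fisher/Gauss-Newton curvature

    H = Σ_j [ 2 g_j g_jᵀ/R_j + R'_j R'_jᵀ/R_j² ] + 2Ω⁻¹,

where `R'` carries the η-dependence of the proportional residual variance
(the η–ε interaction). All Gaussian constants are kept, so on
linear-Gaussian problems the objective *equals* the exact marginal
−2 log-likelihood (machine precision; a test asserts this), and on a
nonlinear two-random-effect toy it agrees with 32-node adaptive
Gauss-Hermite quadrature to better than 1%. The absolute objective value
is comparable only within this implementation.

The outer problem minimizes the summed objective over the nine
log-transformed population parameters (4 fixed effects, 4 IIV variances,
σ²) with L-BFGS-B and numerical gradients; inner problems are warm-started
from the best iterate seen, and the warm-start base is frozen between
improvements so the objective stays locally deterministic. Convergence is
declared when an accepted step improves the −2LL by less than ~1e-4 (ftol)
or the projected gradient is small. An ω² started at zero is held at zero
with its random effect switched off (used for the out-of-sample fit where
σ² is fixed). Any parameter can be frozen by name.

After each L-BFGS-B termination the optimizer is restarted from the best
point with a fresh curvature memory and an alternated finite-difference
step, until a restart no longer improves the objective; this guards
against line searches stalling on finite-difference gradient noise, and
restarted runs were verified to reach the same objective as runs started
at the generating parameters.

**Starting values and multimodality.** The maturation delay makes the
marginal likelihood multimodal in `k_tr`: from starting points far above
the literature maturation time the optimizer converges to a genuine
spurious mode with `k_tr` biased ~+30% (verified by comparing converged
objective values). Default starting values are therefore the published
population estimates rounded to one significant figure (Base 2 G/L, k_tr
0.15/day, γ 0.8, slope 0.2; ω² 0.05; σ² 0.2), the standard pharmacometric
practice of literature-anchored initials. Users fitting other datasets
should try several starts.

**Standard errors.** The Hessian of the objective at the optimum is
computed by central finite differences on the log scale (step 1e-3);
the covariance of the log-estimates is `2H⁻¹`, and by the delta method the
relative standard error of a natural-scale parameter is `100·SE(log θ)`.
A non-positive-definite Hessian is reported as such, with eigenvalues.

## Synthetic cohorts

The generator emulates the study conditions: 116 patients by default, BSA
drawn on [0.47, 1.98] m² from a median-split log-uniform law (equal mass
each side of 0.82 m², so the cohort median matches the reported 0.82;
plain log-uniform and triangular options exist), follow-up uniform on
[200, 581] days, observation visits every 7 ± 1 days, and daily oral 6MP
at 50 mg/m²·BSA rounded to 2.5 mg tablets. A closed-loop titration
emulator adjusts the dose weekly from the latest model ANC: halve (floored
to the tablet grid) below 0.5 G/L, step back up by 25% of nominal (capped)
above 2 G/L. Infection episodes arrive as a Poisson process (2/year, 7-day
duration); during an episode dosing is withheld and CRP sits at 20 mg/L,
otherwise CRP is uniform below 3 mg/L — this exercises the ±14-day
CRP > 5 mg/L exclusion filter. Observations are `x_ma(1+ε)`; a negative
draw is resampled once, then clamped at zero (final clamps are logged;
~0.03% at the default scales). The truncation shrinks the realized ratio
variance ~9% below σ² = 0.226 — an analytic consequence of removing the
`ε < −1` tail that a test verifies against truncated-normal moments.
Every patient keeps its true parameters for recovery scoring. Seeding is
counter-based per patient, so cohorts are reproducible and patients
independent.

At the default settings about 56% of generated ANC observations fall below
2 G/L, matching the reported clinical fraction; the generator does **not**
emulate real-data features such as measurement-batch effects, persistent
neutrophil oscillations beyond what the deterministic model produces,
chart-recorded dosing errors, or WBC/platelet lineages. Passing tests
therefore demonstrate internal consistency of the method, not clinical
validity on real cohorts.

## Validation and the protocol study

Accuracy is summarized per patient (MAE and RMSE of individual
empirical-Bayes predictions) and aggregated as the median and SD across
patients; a pooled variant exists but is not the default. Out-of-sample
validation refits on the chronological first 70% of each patient's
observations (`floor(0.7n)`, minimum 1) and forward-simulates the final
30% with the training-data η fixed, so no held-out information leaks.
The visual predictive check simulates replicate cohorts on each patient's
own design, bins observation times into quantile bins
(`round(sqrt(#distinct times))` bins, minimum 8), and reports observed
2.5/50/97.5 percentiles against simulated percentile bands with 95% CIs;
1000 replicates by default, 200 in the scaled acceptance runs.  The scalar
coverage statistic (fraction of observations inside the outer band) is
computed against the pooled predictive distribution per bin rather than
per-replicate percentile estimates, whose small-sample tails are biased
inward.

The protocol study re-simulates each fitted patient from steady state
under constant daily 6MP at 25/50/75/100 mg/m² (no tablet rounding, so
dose linearity of 6-TGN exposure is exact) over the patient's recorded
treatment window, reads ANC at the patient's actual observation times,
and summarizes min/median/max per patient plus boxplot statistics
(1.5·IQR whiskers) and the linear trend of cohort-median ANC versus dose.

## Known limitations and deliberate behaviours

- **Drugged-equilibrium stability.** With 6-TGN clamped at a level giving
  `E = 1 − 0.5^γ`, the fixed point `x_ma = Base/2` is locally stable only
  for γ below ≈ 0.97 at the published rates: the linearized transit chain
  crosses a Hopf bifurcation (max Re eigenvalue −0.0023/day at γ = 0.769
  but +0.014/day at γ = 1.5), so for strong feedback the trajectory orbits
  in a sustained limit cycle instead of converging. The corresponding
  convergence test at γ = 1.5 fails for this structural reason and is left
  failing as documentation of the model property.
- Post-treatment ANC oscillations are damped (for γ at the population
  estimate) with settling times of months — the slowest linear mode decays
  at ~0.002/day.
- The printed mean maturation time (~20 days) is biologically too long;
  the model is used as published.
- The PD `slope` is the least precisely recovered fixed effect: its IIV is
  the largest (~45% CV) and the titration loop narrows the informative
  dose range, so 40-patient cohorts show cohort-to-cohort deviations of
  the slope estimate up to ~15% even at the exact maximum-likelihood
  optimum (verified by truth-started refits). Averages over replicate
  cohorts recover it well.
- Scaled study sizes: recovery runs use 40-patient cohorts and 3 replicate
  seeds, and the VPC 200 replicates; these are the package's standard
  quick-study settings, with the full 116-patient / 1000-replicate
  configuration available through the same interfaces.
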