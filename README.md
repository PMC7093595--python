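# mtsim — population PK/PD simulation of 6MP maintenance therapy

`mtsim` models the neutrophil dynamics of children on oral 6-mercaptopurine
(6MP) maintenance therapy for acute lymphoblastic leukemia. Maintenance
therapy steers the absolute neutrophil count (ANC) into a target window
(0.5–2 G/L) by titrating daily 6MP, but inter-individual variability in
drug handling makes this hard; a fitted patient-specific model lets
clinicians and methodologists explore dosing protocols in silico.

The package is aimed at pharmacometricians and methods researchers: it
provides the mechanistic model, a non-linear mixed-effects estimator, a
synthetic-cohort generator that emulates the clinical study design, and
the downstream validation and protocol-comparison analyses, all as a
tested Python library with a thin CLI.

## The model

A linear PK cascade for oral 6MP feeding its active metabolite 6-TGN,

    dx_gut/dt  = −k_a·x_gut            (+ F·dose impulses)
    dx_6mp/dt  =  k_a·x_gut − k_20·x_6mp
    dx_6tgn/dt =  FM3·k_me·x_6mp − 0.219·BSA^1.16·x_6tgn

drives a transit-compartment model of granulopoiesis,

    dx_pr/dt  = k_tr·x_pr·(1 − slope·x_6tgn)·(Base/x_ma)^γ − k_tr·x_pr
    dx_trk/dt = k_tr·(x_tr(k−1) − x_trk)        k = 1,2,3
    dx_ma/dt  = k_tr·x_tr3 − k_ma·x_ma          (x_ma = ANC, G/L)

with log-normal inter-individual variability on (Base, k_tr, γ, slope) and
a proportional observation error y = x_ma·(1+ε), ε ~ N(0, σ²). Population
parameters are estimated by FOCE with η–ε interaction: nested optimization
of per-patient empirical-Bayes η and population (θ, ω², σ²). See
`docs/methods.md` for assumptions, numerics and limitations.

## Worked example

```python
from mtsim import (CohortConfig, MaintenanceModel, PopulationModel,
                   generate_cohort)
from mtsim.prep import filter_cohort, threshold_summary
from mtsim.validation import accuracy_metrics

pop = PopulationModel.reference()          # published population values
cfg = CohortConfig(n_patients=20, seed=7)  # 20 virtual patients
records, _ = filter_cohort(generate_cohort(pop, cfg, seed=7))
print(f"{threshold_summary(records).frac_below_2:.3f}")   # fraction < 2 G/L

fit = MaintenanceModel(records, ode_step=0.5).fit(maxiter=60)
print(fit.summary())
acc = accuracy_metrics(records, fit)
print(f"median MAE {acc.median_mae:.3f}  median RMSE {acc.median_rmse:.3f}")
```

Output (abridged):

```
0.539
==========================================================
FOCE-I population fit: 6MP maintenance-therapy PK/PD model
==========================================================
patients:   20    observations:   913
objective (-2LL approx): 2483.285
converged: True   outer iterations: 27   evaluations: 380
----------------------------------------------------------
Fixed effects
  Base          2.531
  k_tr         0.1608
  gamma        0.6344
  slope        0.2276
Inter-individual variability (CV%)
  Base          18.29
  k_tr          10.72
  gamma         17.24
  slope         36.63
Proportional error variance: 0.2165
==========================================================
median MAE 0.742  median RMSE 0.932
```

The summary table mirrors the usual population-PK report: fixed effects
(Base in G/L, k_tr in 1/day, γ and slope dimensionless/per mg·L⁻¹),
inter-individual variability as CV%, and the proportional error variance.
On this synthetic cohort the estimates recover the generating values
(Base 2.34, k_tr 0.148, γ 0.769, slope 0.242) to within sampling error,
and the median per-patient MAE/RMSE are on the ~1 G/L scale expected from
a 48% proportional error at ANC ≈ 2 G/L.

The same pipeline is scriptable from the shell:

```bash
mtsim --seed 1 --out-dir out generate
mtsim --out-dir out filter --cohort out/cohort.csv
mtsim --out-dir out fit --cohort out/cohort_filtered.csv
mtsim --out-dir out validate --cohort out/cohort_filtered.csv
mtsim --out-dir out protocols --cohort out/cohort_filtered.csv
```

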