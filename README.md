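# dalbapk

Population pharmacokinetics and dosing simulation for a **single 1,500 mg
intravenous dose of dalbavancin** used as sequencing therapy in chronic
prosthetic joint infection (CPJI) managed with two-stage exchange.

Dalbavancin is a long-acting lipoglycopeptide: one dose given after 1–2 weeks
of standard IV therapy is expected to cover the remaining weeks until
second-stage surgery.  The question this package answers quantitatively is
*for how long, and against which pathogens, does that single dose keep the
unbound drug exposure above the pharmacodynamic target?*  It is written for
PK/PD scientists and infectious-disease pharmacologists who want a tested,
scriptable re-implementation of that analysis chain on sparse
therapeutic-drug-monitoring data.

## What it implements

**Model.** A one-compartment disposition model with zero-order infusion input
and first-order elimination, as a nonlinear mixed-effects model: for subject
*i* and observation *j*

```
V_i  = V_pop  · exp(η_V,i)      η_V,i  ~ N(0, ω_V²)
CL_i = CL_pop · exp(η_CL,i)     η_CL,i ~ N(0, ω_CL²)
y_ij = f(t_ij; V_i, CL_i) · (1 + b·ε_ij)    ε_ij ~ N(0, 1)
```

with concentrations in mg/L, times in hours, V in L and CL in L/h.  The
closed-form profile, windowed AUC (exact analytic integral), unbound-fraction
conversion `fu = 1 − binding/100`, and a two-compartment structural
candidate live in `dalbapk.structural_pk`.

**Estimation** (`dalbapk.nlme`): maximum likelihood by SAEM — an MCMC E-step
over the individual random effects with a stochastic-approximation M-step —
with importance-sampling OFV (−2 log L), AIC/BICc, empirical Bayes estimates,
η-shrinkage, and relative standard errors via a stochastic (Louis-type)
Fisher information.  Structural model selection ranks candidates by BICc.

**Diagnostics** (`dalbapk.diagnostics`): subject-level non-parametric
bootstrap (vectorised so 1,000 refits are cheap), normalised prediction
distribution errors (NPDE) with per-subject decorrelation, a
prediction-corrected visual predictive check (pc-VPC), and goodness-of-fit
tables (PRED / IPRED / IWRES).

**Covariate search** (`dalbapk.covariates`): CKD-EPI (2009) eGFR and
Cockcroft–Gault CrCL, plus a forward-inclusion (ΔOFV > 3.84, p<0.05) /
backward-elimination (ΔOFV > 6.63, p<0.01) stepwise procedure on V and CL
with a complete decision log.

**Target attainment** (`dalbapk.pta`): Monte Carlo simulation of individual
(V, CL) profiles and probability of target attainment,

```
PTA(binding, day, MIC) = % of profiles with fu · AUC[24·day, 24·day+24] / MIC ≥ 50
```

over protein binding 93–99%, days 21/27/35 post-dose and MIC 0.002–0.25
mg/L (a stasis target of 25 is also provided).  PTA ≥ 90% is flagged optimal.

**Synthetic cohort** (`dalbapk.cohort`): because the underlying patient data
are not public, a generator emulates the study design (18 elderly subjects,
one 1,500 mg infusion over 0.5 h or 2 h, 1–3 trough samples between days 8
and 30, preserved renal function, normal albumin), and a deterministic
20-patient clinical fixture reproduces the cohort's published aggregate
counts (70% female, 11 hip / 6 knee / 2 shoulder / 1 ankle, 24 isolates of
which 17 CoNS, 94.7% microbiological cure).

**Pipeline & CLI** (`dalbapk.io`, `dalbapk.cli`): long-format CSV dataset
I/O, YAML configuration, and a `dalbapk` command with subcommands
`simulate-cohort`, `fit`, `diagnose`, `bootstrap`, `covariates`, `pta`,
`report` and `run-all`.

## Worked example

```python
from dalbapk import (REFERENCE_MODEL, PtaScenario, StudyDesign, fit_saem,
                     generate_pk_dataset, initial_estimates, pta_table)

# 1. a synthetic sparse cohort at the study design, then refit it
ds = generate_pk_dataset(StudyDesign(), REFERENCE_MODEL, seed=1)
fit = fit_saem(ds, initial_estimates(ds), seed=7)
print(fit.theta, fit.omega, fit.b, fit.ofv)

# 2. target-attainment table under the published final model
print(pta_table(REFERENCE_MODEL, PtaScenario()).to_markdown())
```

The fit on this 18-subject, 23-observation cohort prints

```
V_pop  = 19.9 L
CL_pop = 0.0371 L/h
omega_V, omega_CL = 0.147, 0.105
b = 0.127   OFV = 140.6 (MC SE 0.10)
```

i.e. the fixed effects land close to the generating values (V 17.9 L,
CL 0.036 L/h) while the variability parameters are noisy at this sparsity —
expected for 1–3 troughs per subject.  The PTA table prints

```
| Protein binding | Day | <=0.03 | 0.06 | 0.125 | 0.25 |
|---|---|---|---|---|---|
| 93% | Day 21 | 100.0* | 100.0* | 100.0* | 99.6* |
| 93% | Day 27 | 100.0* | 100.0* | 99.6* | 96.4* |
| 93% | Day 35 | 99.9* | 99.2* | 96.2* | 85.4 |
| 95% | Day 21 | 100.0* | 100.0* | 99.9* | 98.8* |
| 95% | Day 27 | 100.0* | 99.9* | 98.8* | 91.0* |
| 95% | Day 35 | 99.9* | 98.4* | 92.0* | 71.5 |
| 97% | Day 21 | 100.0* | 100.0* | 99.2* | 89.8 |
| 97% | Day 27 | 99.9* | 99.3* | 94.9* | 69.3 |
| 97% | Day 35 | 98.9* | 95.6* | 80.9 | 35.6 |
| 99% | Day 21 | 99.9* | 97.1* | 62.4 | 0.7 |
| 99% | Day 27 | 98.1* | 86.6 | 29.7 | 0.0 |
| 99% | Day 35 | 89.2 | 62.2 | 8.9 | 0.0 |
```

Read: at the most favourable binding (93%) the single dose keeps
fAUC0-24/MIC ≥ 50 for ≥ 90% of simulated patients through week 5 for
MIC ≤ 0.125 mg/L and through week 4 at the staphylococcal breakpoint
(0.25 mg/L).  At 99% binding the free-drug margin collapses at higher MICs.

**A caveat on the 99%-binding block.**  Under the literal convention used
here (unbound AUC over the 24 h window starting at hour 24·day, scaled by a
fixed fu), the higher-MIC cells of the 99%-binding block come out far lower
than the corresponding published table (e.g. 0.7% vs 65.9% at day 21 / MIC
0.25): the typical profile's fAUC24 at day 21 is ≈ 7.1 mg·h/L against a
required 12.5, so no windowing-free reading can push PTA above 50%.  The
93–97% blocks reproduce closely, which suggests the extreme column was
produced under a different unstated convention (window placement, variances
vs SDs, or parameter-uncertainty sampling).  We do not guess; the
discrepancy is documented rather than tuned away.

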