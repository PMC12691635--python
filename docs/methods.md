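# Methods

This note documents the model, the algorithms and their settings, the
synthetic-data generator, and the design decisions taken where more than one
defensible choice existed.  Units are fixed package-wide: hours, mg, L,
mg/L, mg·h/L.

## Structural model

The final model is a one-compartment disposition model with zero-order
(constant-rate) infusion input and first-order elimination.  For a dose of
amount `D` infused over `T_inf` starting at `t0`, the concentration is the
difference of two step responses — an infusion switched on at `t0` and an
equal one switched off at `t0 + T_inf`:

    S(τ) = (1/CL) · (1 − e^{−kτ}),  k = CL/V,  τ > 0
    C(t) = R0 · [S(t − t0) − S(t − t0 − T_inf)],  R0 = D/T_inf

Multiple doses superpose (linearity).  The cumulative AUC has the analytic
form `∫S = (τ + (e^{−kτ} − 1)/k)/CL`, so windowed AUCs are exact and the
infinite-horizon exposure reduces to `ΣD/CL`, which doubles as a free test
oracle.  `1 − e^{−x}` is evaluated as `−expm1(−x)` to avoid cancellation at
small `kτ`.

A two-compartment candidate (parameters V1, CL, Q, V2) is provided for
structural model selection.  Its eigenvalues are computed with the stable
product form `λ1·λ2 = k10·k21` (the quadratic-formula difference cancels
catastrophically when the peripheral compartment is weakly coupled), and a
small floor on `λ1 − λ2` handles the repeated-root limit.

Observations below the 1.0 mg/L quantification limit are flagged on read and
excluded from the likelihood.  This is a simple-exclusion policy, not a
censored-likelihood (M3-type) treatment; the cohort's troughs sit far above
the limit, so the choice is inconsequential here and is stated for
transparency.

Infusion duration is recorded per subject (0.5 h and 2 h both occur in the
emulated cohort) and used as recorded in all predictions.

## Mixed-effects model and SAEM

Log-individual parameters are linear in covariates plus a random effect:
`log φ_i = X_i β + η_i`, `η_i ~ N(0, diag(ω²))`, with proportional residual
error `y = f·(1 + b·ε)`.  Estimation is in log space throughout (log V,
log CL, log ω, log b), which enforces positivity without constraints.

SAEM alternates:

* **E-step** — per subject and chain (2 chains), one Metropolis proposal
  drawn from the random-effect prior (its acceptance ratio needs only the
  data likelihood) followed by 2 adaptive random-walk proposals whose scale
  targets ≈ 35% acceptance (`scale ∝ exp(0.05·(acc − 0.35))`).
* **SA accumulation** — the complete-data model is exponential-family here,
  so the sufficient statistics are `Σ x φ`, `Σ φ²` per parameter and the
  summed squared proportional residuals; they are averaged over chains and
  relaxed with step `γ_k`.
* **M-step** — closed form: a per-parameter linear solve for β, variance
  updates for ω², and `b² = Σr²/N`.

The schedule is 500 exploration iterations at `γ = 1` followed by 200
smoothing iterations with `γ_k = k^{−0.7}` (configurable).  During
exploration the variance parameters carry a simulated-annealing floor
(`var ≥ 0.95 · previous`) that prevents premature collapse of ω or b.
Initial values come from a naive pooled analysis: the elimination rate from
a pooled log-linear regression of concentration on time, V from
back-extrapolated `dose/C0`, `CL = k·V`.

Convergence is declared post hoc: the relative drift of every parameter
trace over the last 20% of the smoothing phase must be small, and no freely
estimated ω may collapse below 1e-4; violations flag the fit rather than
raising.  With all ω fixed at 0 the model degenerates to a pooled nonlinear
regression and is maximised directly (Nelder–Mead) instead of sampled.

The engine carries a leading batch axis: bootstrap resamples and
replicate-study fits share one vectorised SAEM pass, which is what makes
1,000-resample bootstraps and 20-replicate recovery studies run in seconds.

## Likelihood, information criteria, standard errors

The marginal likelihood is estimated by importance sampling: per subject, a
multivariate-t proposal (df 4) centred at the conditional mode of η with the
inverse conditional Hessian as scale; the Monte-Carlo SE is reported.  A
Laplace approximation is available as a deterministic alternative and is
what the stepwise covariate search uses for its ΔOFV decisions — candidate
comparisons then carry no simulation noise and the decision log is exactly
reproducible.  The reported OFV of a fit remains the importance-sampling
estimate.

AIC = OFV + 2p.  BICc uses the mixed penalty appropriate for nonlinear
mixed-effects models: parameters attached to subject-level random effects
(fixed effects with IIV, the ω's) are penalised with log(n_subjects), purely
observation-level parameters (b, and fixed effects without IIV) with
log(n_obs).

Relative standard errors default to a stochastic observed Fisher information
(Louis' identity): the score and Hessian of the complete-data log-likelihood
are closed-form for this family, and their conditional moments are
accumulated over a 500-iteration MCMC run at the final estimates.  A
finite-difference Hessian of the Laplace log-likelihood is the fallback
(`method="linearized"`; step 0.05 in log-parameters, large enough that OFV
differences dominate inner-optimisation noise).  In the ω = 0 limit both
reduce to the direct regression information, computed exactly in that
branch.  Log-scale SEs are reported directly as relative SEs (delta method).

Shrinkage is `100·(1 − SD(EBE η)/ω)` with the sample SD (ddof 1).  At the
emulated sparsity (1–3 troughs per subject) shrinkage is substantial — V
typically 30–70% — and the EBE-vs-truth correlation for η_CL sits around
0.65–0.75; both are properties of the design, not of the estimator.

## Diagnostics

* **Bootstrap**: subjects resampled with replacement (no stratification —
  single-arm cohort), each replicate refit with a reduced budget (150 + 75
  iterations) initialised at the base estimates.  Reusing the base fit as
  the initial value is a deliberate runtime trade-off; it would bias
  replicates if the likelihood were multimodal, which the profile checks on
  this model did not show.  Medians and 2.5/97.5 percentiles use type-7
  (linear-interpolation) quantiles.  Replicates whose fixed-effect traces
  drift or whose ω collapses are dropped and counted; >10% drops raise a
  warning in the result.
* **NPDE**: K = 1000 simulated replicates per subject (IIV + residual
  error), per-subject decorrelation by the Cholesky factor of the simulated
  covariance, ranks with half-rank tie handling, inverse-normal transform.
  Global tests: t-test for mean 0, chi-square for variance 1, Shapiro–Wilk
  for normality, combined with a Bonferroni factor of 3.  K < 100 is
  refused (rank resolution).
* **pc-VPC**: 500 simulations by default; prediction correction multiplies
  each observation (and its simulated counterparts) by bin-median PRED /
  own PRED; observed 10/50/90th percentiles are compared with simulated 90%
  CIs.  Default bins are weekly (168 h); bins with fewer than two
  observations merge rightwards and the merge is recorded.  The binning and
  test choices here are conventional, not taken from any specific source
  analysis.
* **GOF**: per-observation PRED (population), IPRED (EBE-based),
  `IWRES = (DV − IPRED)/(b·IPRED)`, optionally joined with NPDE, emitted as
  TSV.

## Covariate search

Continuous covariates enter as power functions normalised to the cohort
median (`(cov/ref)^β`); sex enters exponentially (`e^{β·I(female)}`,
reference male), reported as the proportional shift `e^β − 1`.  Both forms
keep the M-step linear in log space.  Forward inclusion adds the candidate
with the largest ΔOFV above 3.84 (χ²₁, p<0.05); backward elimination removes
any effect whose deletion costs less than 6.63 (p<0.01).  Ties break by the
larger reduction in the corresponding ω, then alphabetically.  Every tested
(parameter × covariate) pair lands in the decision log with its ΔOFV; a
`plausibility` column is left blank for manual scientific review — the
procedure implements only the quantitative criteria.  The CKD-EPI equation
omits the race coefficient (the emulated cohort is not stratified by race).

## Monte Carlo target attainment

1,000 (V, CL) pairs are drawn from the fixed effects and log-normal IIV.
Three deliberate conventions:

* `fAUC0-24` at day D is `fu ×` AUC over `[24·D, 24·D + 24]` hours after
  dose start — the most literal reading of "day D post-dose".
* No residual error and no parameter-uncertainty sampling: PTA reflects
  inter-individual variability only.
* Protein binding is a fixed scalar per scenario (fu = 0.07, 0.05, 0.03,
  0.01), not sampled.

PTA = percentage of profiles with fAUC24/MIC at or above the target ratio
(50 for ~1-log10 kill, 25 for stasis); ≥ 90% is flagged optimal.  The full
doubling MIC grid 0.002–0.25 mg/L is retained internally; reports show the
columns ≤0.030 / 0.060 / 0.125 / 0.250.  The shipped scenario seed (12345)
makes the published tables bit-reproducible; the IIV SD of simulated log-CL
converges to ω_CL by the law of large numbers, which the tests exploit.

Under these conventions the 93–97% binding blocks reproduce the reference
table within Monte-Carlo noise, while the higher-MIC cells of the 99% block
do not and cannot: the typical profile's day-21 fAUC24 at fu = 0.01 is
≈ 7.1 mg·h/L against the 12.5 required at MIC 0.25, so PTA must fall below
50% regardless of the random-effect draw.  The extreme column evidently
encodes an additional unstated convention; we document rather than
reverse-engineer it, and check that block for monotonicity only.

A repeated-dosing scenario (doses spaced 4 weeks) is expressible through
dose superposition but ships only as an example configuration, not as an
analysed claim.

## Synthetic data: what it does and does not emulate

`generate_pk_dataset` draws, per subject: one 1,500 mg dose (infusion 0.5 h
or 2 h, alternating to mirror the two participating centres), a sample count
of 1–3 with probabilities (0.70, 0.25, 0.05) — mean ≈ 1.35, matching ~23
concentrations over 18 subjects — sampling days uniform within the windows
8–14, 18–23 and 26–30 (one window per sample, without replacement), and
covariates from an elderly cohort profile (age ≈ N(75.5, 7), 70% female,
normal albumin, creatinine consistent with preserved renal function; eGFR
and CrCL derived from the formulas above).  Concentrations are exact model
predictions with proportional noise, BLQ-flagged below 1.0 mg/L.

It does **not** emulate: covariate–parameter correlations (the generating
model has none — which is what makes the null covariate-search calibration
meaningful), clinically triggered sampling times, assay error beyond the
proportional term, dropout, or repeat dosing.  Passing tests therefore
validate the estimator and pipeline under the design's information content,
not the clinical findings themselves.

The 20-patient clinical fixture is deterministic.  Its aggregate counts are
faithful to the reported cohort; its patient-level free fields (exact ages,
intervals, follow-up, renal values) are synthetic, constructed so the type-7
medians and interquartile intervals land on the reported summaries, and are
labelled as such.  Isolate-level MICs are not in the fixture because none
were reported per isolate.

## Identifiability at the study design

Trough-only sampling identifies CL well (the terminal slope is sampled
directly) but V only through back-extrapolation over 200–700 h.  In
replicate studies at this design the ML estimate of V itself occasionally
lands 30–55% from the generating value with a genuinely better likelihood
there (profile-likelihood-verified), and ω_V is frequently underestimated.
Median recovery across replicates is unbiased within a few percent.  Users
fitting real sparse troughs should treat single-dataset V estimates (and
anything derived from ω_V) with corresponding caution; the bootstrap CI, not
the point estimate, is the honest summary.

## Numerical conventions and degenerate inputs

* Quantiles: type 7 everywhere (numpy default); even-n medians are the mean
  of the middle pair.
* Predictions are floored at 1e-12 before entering the proportional-error
  likelihood; ω at 1e-12 in priors; proposal scales clipped to [1e-3, 10].
* Empty observation vectors: subjects without quantifiable observations are
  rejected for estimation, return the prior mode (η = 0) as EBE, and are
  absent from GOF tables.
* `t2 = inf` is an explicit sentinel in `auc_window`; reversed windows,
  negative times, out-of-range binding and non-positive parameters raise
  domain errors rather than propagating NaN.
* Ranking ties in model selection break by parameter count (fewer wins).

## Known limitations

* Diagonal Ω only (no η covariance), no inter-occasion variability; additive
  and combined error models are not offered as final models.
* The NPDE decorrelation uses the simulated covariance at K = 1000; very
  small K would make the Cholesky unstable (hence the K ≥ 100 refusal).
* The Laplace OFV inherits the usual small-sample optimism for variance
  parameters; RSEs for ω and b are rough at n = 18 (their Louis estimates
  carry 20–60% RSE themselves).
* The stepwise search tests one effect at a time and cannot discover
  jointly-significant covariate pairs that are individually null.
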