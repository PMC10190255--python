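# Methods

This note documents the models, statistics and design choices behind
`meropk`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic-data results do and do not show.

## Model representation

A candidate PopPK model is a declarative spec: structural compartment
model (1 or 2 compartments, clearance–volume parameterization CL, V1, Q,
V2), typical values θ, covariate effects, an IIV covariance matrix Ω on
the log scale, and one or more residual-error models σ. Canonical units
are h, mg, L, mg/L, L/h, mL/h for flow rates and mL/24 h for residual
diuresis; spec files record original units where they differ.

Covariate effects support four functional forms — additive slope
(`linear`), `power`, fractional change (`proportional-shift`) and
`categorical-factor` — applied to their θ in declaration order, which the
loaders preserve. Inter-individual variability is multiplicative
log-normal, `P_i = P_typ · exp(η_i)`, the universal PopPK convention;
η = 0 reproduces the typical parameters bit-for-bit. Residual error is
`y = f·(1 + ε_prop) + ε_add` with centered normal ε; simulated negative
observations are truncated at zero and counted.

The eight bundled candidates follow the published structural facts (six
two-compartment models; total flow rate on CL in Burger 2018; residual
diuresis on CL in O'Jeanson 2021 and Ulldemolins 2015; eGFR on CL in
Niibe 2020 and Hanberg 2018) and reproduce each model's published typical
clearance at the reference covariates (e.g. O'Jeanson 5.78 L/h at zero
residual diuresis, Burger 4.7 L/h at 2,000 mL/h total flow, Niibe
4.4 L/h at eGFR 31). Quantities the evaluation literature does not print
(peripheral volumes, Ω, σ, covariate slopes) are plausible
reconstructions and are flagged as such in each spec's `provenance`
field; conclusions that depend on those values (e.g. absolute NPDE
variance of a candidate on real data) should not be drawn from the
bundled specs alone.

## Concentration prediction

Profiles are exact analytic solutions. For a zero-order input of rate R
and duration T the central concentration is

    C(t) = R · Σ_i (A_i/λ_i) · (1 − e^{−λ_i · min(t,T)}) · e^{−λ_i · max(t−T,0)}

with one exponential (λ = CL/V1, A = 1/V1) or two (λ = α, β from the
standard two-compartment micro-constants, A the usual macro-constants).
Dosing histories superpose linearly; continuous infusion is one long
event per bag, not a special mode. When α and β coincide within a 1e-9
relative gap (possible only in the k12 → 0 limit), k21 is perturbed by
1e-6 and the event logged rather than dividing by α − β ≈ 0. Agreement
with an independent stiff ODE integration is within 1e-6 relative
tolerance across randomized parameter sets (tested).

## Forecasting

*A priori* predictions evaluate the noise-free profile at η = 0 after
per-model covariate imputation. The MAP estimate minimizes

    Σ_j [(y_j − f_j(η))²/g_j² + ln g_j²] + ηᵀΩ⁻¹η,  g_j² = σ_add² + σ_prop²f_j²

by Nelder–Mead with a BFGS polish, multistarted from η = 0 plus four
jittered starts drawn with a fixed seed (objective tolerance 1e-8), so
the estimate is deterministic given its inputs; non-convergence returns
the best point found, flagged. A variance floor of 1e-10 keeps the
likelihood finite as f → 0. The ln g² term makes the objective an exact
posterior mode for the declared error model — including the known
consequence that proportional error slightly favors lower predictions.

The Bayesian arm conditions on exactly one sample — the last (trough)
measurement of occasion 1 — and reports the individual prediction at the
MAP η for the occasion-2 trough. A "trough" is operationalized as the
last observation within an occasion; an occasion is the interval holding
at least one measurement between dosing events, with dose events lacking
an intervening measurement merged. Continuous infusion without bag
changes has no internal dose events, so occasions are split at midpoints
between consecutive samples. Multi-sample conditioning exists
(`map_estimate` accepts any observation subset) but is off by default,
mirroring the real-world single-TDM scenario.

## Evaluation statistics

Per sample, PE = (c_pred − c_obs)/((c_pred + c_obs)/2): symmetric,
scale-free, bounded in (−2, 2). MPE = median(PE)·100 (accuracy),
MAPE = median|PE|·100 (precision); medians use linear interpolation
between order statistics (numpy default) for bit-for-bit
reproducibility. Records with non-positive observations are excluded
before PE and counted.

The 95% CI of the MPE is a nonparametric percentile bootstrap with 1,000
resamples drawn over *subjects*, which respects within-subject
correlation; the seed is part of the configuration. Acceptance verdicts:
accuracy iff −20% ≤ MPE ≤ 20% with the CI spanning zero; precision iff
MAPE ≤ 30%.

## Diagnostics

**NPDE.** Per subject, K replicate observation vectors are simulated
under the full model (default K = 1,000); the observed vector and the
replicates are decorrelated with the empirical simulated mean and the
Cholesky square-root of the simulated covariance (ridge-repaired and
logged if singular). pd, the fraction of decorrelated replicates below
the decorrelated observation, is clamped to [1/(2K), 1 − 1/(2K)] so the
normal quantile stays finite. Tests: one-sample t-test of mean 0, a
Fisher-type χ² variance test of variance 1, and a global Shapiro–Wilk.
Under the generating model the observed type-I error of the mean and
variance tests is close to the nominal 5% (measured 6–7% over 100
replicate experiments of 40 subjects at K = 300).

**pcVPC.** Observations and simulated replicates (default K = 500) are
rescaled by bin-median population prediction over bin-specific
predictions; bins are 8 quantile-spaced intervals of time after the most
recent dose (time since infusion start for continuous infusion) unless
explicit edges are given; empty bins are dropped with a warning. Ribbons
are the 2.5/97.5 percentiles across replicates of each bin's 5th/50th/
95th percentile. On self-simulated data the observed percentiles fall
inside the 95% bands in ≈95% of bins (tested).

## Synthetic cohorts

The generator emulates the structure of the two-center evaluation
dataset: 73 subjects (60/13 per center), 56 intermittent / 17 continuous
infusion with the retrospective center all-continuous, dialysis modality
mix ≈ 59/32/10% CVVH/CVVHD/CVVHDF, and covariates drawn from
median/range-calibrated families — log-normal for weight, creatinine and
flow rate; truncated normal for age, height and albumin; zero-inflated
log-normal for residual diuresis in center 1 and the three-level
categorical classes (mapped to lower limits 1,000/500/0 mL/24 h) in
center 2. The moment-matching heuristic sets log-normal σ to
(ln hi − ln lo)/5 and truncated-normal scale to (hi − lo)/5, treating a
~73-subject range as ±2.5 SD, then truncates at the declared bounds.

Dosing regimens are configurable templates, not published values:
1,000 mg over 0.5 h every 8 h (intermittent) and 3,000 mg/24 h
(continuous). Sampling is one trough per occasion, two occasions per
subject with a ~15% chance of a third, matching the ~2.6 samples/subject
and the 11-of-73 subjects with more than two samples. Every generated
subject passes the inclusion filter (≥24 h CRRT after the first dose,
≥2 samples in ≥2 occasions) by construction, and cohorts are
byte-identical per seed.

What passing self-simulation tests show — and what they do not: they
demonstrate that the forecasting, scoring and diagnostic machinery is
internally calibrated (unbiased under the generating model, improved by
conditioning, nominal NPDE/pcVPC behavior). They do not validate any
candidate model against real CRRT patients: the virtual cohorts have
trough-only sampling, constant covariates, no time-varying CRRT
settings, no assay-specific error structure, and residual-diuresis
categories assigned by a simple probability mix.

## Numerical and design choices

- Missing model-relevant covariates are imputed per evaluated model with
  that model's declared population median (e.g. 845 mL/24 h residual
  diuresis for O'Jeanson); imputation never overwrites observed values
  and is idempotent.
- eGFR: Cockcroft–Gault `((140 − age)·wt)/(72·Scr)` (×0.85 female) in
  mL/min; CKD-EPI 2009 creatinine equation (race term omitted) in
  mL/min/1.73 m². Both are derived on the fly from age, weight,
  creatinine and sex.
- Simulation sizes in the test suite are chosen to characterize the
  statistics at desk scale: 500 subjects for the calibration checks, 100
  replicate experiments of 40 subjects for the NPDE type-I error, 300
  subjects for pcVPC coverage.
- Known limitation: with 40–50% IIV the median of the symmetric PE of
  occasion-2 trough forecasts under self-simulation is slightly negative
  (≈ −3% at 500 subjects) — a curvature effect of the statistic plus MAP
  shrinkage, not an implementation bias; the a-priori MPE over all
  samples remains CI-consistent with zero.
- Models with several published residual-error variants (Burger 2018:
  combined, proportional, additive) are evaluated as separate arms.
- Reports are CSV plus a JSON manifest (package version, configuration,
  seeds, exclusions) that fully determines the outputs; plots are
  optional artifacts, never inputs to computation.
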