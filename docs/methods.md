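# Methods

`longdens` implements a longitudinal measure of mammographic breast
density from serial BI-RADS readings, and the machinery to evaluate how
much predictive information for invasive breast cancer such a measure
carries relative to the raw readings. This note documents the model,
the estimators, the synthetic-cohort generator, the numerical choices,
and the limits of what the simulation studies can show.

## The density mixed model

A woman's BI-RADS density reading at a screen (A–D, coded 1–4 and
treated as a continuous outcome) is modelled by a linear mixed model on
age and body-mass index:

    y_ij = x_ij' β + z_ij' b_i + ε_ij,
    b_i ~ N(0, G),   ε_ij ~ N(0, σ²),

with fixed-effects row
`x = (1, a, a², a³, a⁴, bmi, a·bmi)` where `a = age/5 − c` is age in
5-year units centred at a constant `c`, and random-effects row
`z = (1, a)` giving each woman a random intercept and random age slope
with unstructured 2×2 covariance `G`. The quartic age polynomial lets
the population mean surface bend over the 40–75 age range; the single
interaction term lets the age gradient vary with BMI.

Parameters and defaults:

| parameter | meaning | unit | default |
|---|---|---|---|
| `centering` (c) | age centering constant | 5-yr units | 10 (= age 50) |
| `β` | fixed effects | density units | estimated |
| `G` | random intercept/slope covariance | density², density²/5yr² | estimated |
| `σ²` | residual (reading) variance | density² | estimated |

The centering constant conditions the quartic terms numerically;
fitted values are invariant to it (tested to 1e-6). BMI is winsorized
at 15 and 35 kg/m² before modelling, so that extreme adiposity
contributes no further gradient; missing baseline BMI is imputed by the
mean observed baseline BMI in the woman's 5-year baseline-age bin
(configurable width; the bin scheme is this package's choice — only
"given the woman's age at baseline" is externally specified), and
missing follow-up BMI is carried forward from her last observed value.

### Fitting

The model is fitted by maximum likelihood (not REML; REML is available
behind a flag for sensitivity). The marginal likelihood is a product
over women of multivariate normals with covariance
`V_i = Z_i G Z_i' + σ² I`; women are batched by screen count so the
per-woman linear algebra runs as stacked Cholesky factorizations. β is
profiled out by generalized least squares at each variance-component
candidate, and the optimizer works over the Cholesky factor of `G` and
`log σ`, so positive semidefiniteness holds by construction. A
Nelder–Mead warm start followed by L-BFGS-B polishing is used, with a
relative log-likelihood tolerance of 1e-10 and an iteration cap.
Cluster-robust (sandwich) standard errors `A⁻¹BA⁻¹` are computed by
central finite differences of the per-woman log-likelihoods over the
full parameter vector (β, vech G, σ²) — an 11×11 matrix, with the β
block reported by default. If every woman has a single screen the fit
proceeds but flags `G` as unidentified.

## Sequential empirical-Bayes density

The longitudinal density of woman i at her k-th screen is the model
prediction using her readings up to and including that screen:

    b̂_i = G Z' V⁻¹ (y − Xβ)  over screens 1..k,
    d_ik = x(age_ik, bmi_ik)' β + z(age_ik)' b̂_i.

This is the posterior mean (BLUP) of her random effects under the
population prior: with no history the estimate is the population
age–BMI surface (borrowing strength from other women of the same age
and BMI), and with a long history it converges to her own trajectory.
Estimates use only data observed to that point (no lookahead, tested),
include the current reading (an exclusive variant is available), use
the current possibly-imputed BMI for the fixed part, and are not
clipped to [1, 4] — the categorical measure absorbs the tails.

### The eight-category measure

Continuous estimates are cut into eight categories for interpretability.
Cut points are the empirical quantiles (inverse CDF, lower value at
ties) of the baseline estimates at cumulative probabilities
`(p₁/2, p₁, p₁+p₂/2, …, p₁+p₂+p₃+p₄/2)`, where `p₁..p₄` are the
baseline BI-RADS proportions — so categories 1–2 together match
BI-RADS A with an equal split inside, and so on. Categories are
left-closed/right-open (a value on a threshold goes up). The published
thresholds (1.5, 2.0, 2.2, 2.6, 2.9, 3.2, 3.6) are shipped as
`CutPoints.paper_default()` but are only meaningful together with a
compatible parameter file; cut points are re-derived whenever the model
is refit. If a BI-RADS category is empty at baseline, repeated
quantiles are nudged apart by one ulp to keep the thresholds strictly
increasing (degenerate but well-defined output).

## Survival evaluation

Cohorts are expanded into counting-process risk intervals on the
follow-up time scale: each woman enters 6 months (configurable) after
her baseline screen, covariates are piecewise constant taking at time t
the values of her latest screen at or before t, and the final interval
carries her event indicator. Three proportional-hazards models are
fitted, each adjusted for age at the entry screen (continuous, per
year) and time-varying BMI:

1. BI-RADS density as a 4-level factor, reference "Scattered" (2) — 3 df;
2. continuous longitudinal density, linear + quadratic — 2 df;
3. the eight-category measure as a factor, reference category 3 — 7 df;

plus the age+BMI-only reduced model. The information gain of a density
measure is ΔLR-χ² = 2(ℓ_full − ℓ_reduced). A secondary analysis starts
follow-up at the third mammogram (women with fewer screens excluded;
the age covariate is then age at the third mammogram), and a frozen
variant holds density and BMI at a given screen's values through
follow-up.

The partial-likelihood fitter is this package's own Newton–Raphson with
step-halving, Efron tie handling by default (Breslow available; event
times are continuous in simulation so ties are rare). Risk-set sums use
a suffix-sum decomposition (sums over `stop ≥ t` minus sums over
`start ≥ t`), making an iteration linear in the number of rows.
Convergence is score max-norm < 1e-9 or log-likelihood change < 1e-11.
A coefficient exceeding 20 in magnitude aborts with a separation error
naming the covariate; the factor density models relax this bound
because, at simulation scale, a low-risk category can contain no events,
making its dummy's partial likelihood monotone — the likelihood still
converges to its supremum, so ΔLR remains valid, and the covariance
falls back to a pseudo-inverse with an enormous variance for that level.
Density and density² enter uncentred so hazard ratios read per unit.

## Concordance and stability

Discrimination is a windowed incident/dynamic concordance index: in
each window [t, t+1) starting at t = 0.5 years, every pair (event at
time s, subject at risk at s without an event at s) scores 1 if the
case's current linear predictor is larger, ½ if tied; yC(t) is the
scored fraction, and the summary `mean_yC` weights windows by
comparable-pair count (an equal-weight variant exists). The per-window
standard error treats events as independent clusters of pairs. Model
comparison bootstraps whole women — intervals within a woman are
dependent — and reports the percentile interval of the `mean_yC`
difference; it is deterministic under a fixed seed. This windowed
definition, with current covariate values and pair-count weighting, is
this package's operational definition of the yearly concordance curve.

Stability: for women with at least three mammograms, per-woman relative
risks at the second and third screen are computed from the fitted
density coefficients only (factor HRs for BI-RADS; linear+quadratic
terms for longitudinal density), each screen's risks are normalised to
mean 1 across women, and a woman is "unstable" when the ratio
RR₃/RR₂ leaves [4/5, 5/4].

## The synthetic-cohort generator

No individual-level screening data are distributable, so every analysis
runs on synthetic cohorts with known truth. The generator emulates a
US-style screening cohort:

- baseline age uniform on 40–73; each woman's screens arrive at
  Gaussian-jittered intervals (mean 1.8, SD 0.4, floor 0.3 years) with
  a geometric stopping rule (continuation probability 0.78, cap 10),
  which after censoring reproduces a median of 3 observed mammograms,
  ~22% of women with a baseline mammogram only, and a median ~6 years
  of follow-up;
- true BMI starts at 27 + 0.05·(age₀ − 50) kg/m² with SD 5 and follows
  a drifted random walk (+0.1 kg/m²/yr, walk SD 0.3/√yr); the recorded
  BMI is missing with probability 5% at baseline and 16% at follow-up,
  exercising the imputation path;
- latent density is the mixed-model surface (β giving mean ≈ 2.65 at
  age 50/BMI 27, declining ≈ 0.5 units to age 73, BMI gradient −0.05
  per kg/m²; G = [[0.55, −0.02], [−0.02, 0.02]]; σ² = 0.15) evaluated
  at *winsorized* true BMI — the generating truth adopts the same
  adiposity plateau the analysis assumes — chosen to reproduce baseline
  BI-RADS proportions near (8, 35, 43, 14)% and a ~30–40% chance that
  consecutive readings differ;
- the observed reading is the latent value plus N(0, σ²) noise, rounded
  and clipped to 1–4 (a continuous-outcome mode skips the rounding);
- invasive-cancer times are piecewise-exponential with log-hazard
  driven by the TRUE latent density (per-unit log-HRs ln 5.53 and
  ln 0.83 for the linear and quadratic terms), baseline age (0.04/yr)
  and winsorized BMI (0.005 per kg/m²), with baseline rate 0.003/yr at
  the reference woman (density 2.6, age 50, BMI 27), giving ~2.5%
  cumulative incidence; censoring at the earliest of 15 years, age 75,
  or 3 years after the last screen. Screens scheduled after exit are
  discarded (the baseline screen is always kept).

Driving the hazard by the *latent* density rather than the noisy
reading is deliberate: it is precisely the regime in which smoothing a
woman's reading history toward her latent trajectory should recover
predictive information, which is the method's motivation.

What the generator does **not** emulate: calendar effects,
radiologist/machine reading effects, hormone-therapy dynamics, race
stratification, a skewed (younger-heavy) baseline-age distribution,
and informative participation. Passing tests therefore show that the
estimators are correct and that the method behaves as designed when its
assumptions hold — not that the same quantitative gains would be
observed in any particular clinical cohort.

## Experiment designs in the test suite

- **Oracle equivalence.** Sequential EB estimates are checked to 1e-8
  against Henderson's mixed-model equations (an algebraically different
  route), and the one-observation posterior against 2-D quadrature to
  1e-4. The Cox fitter is checked against a grid-search maximizer of a
  hand-coded partial likelihood and against lifelines'
  `CoxTimeVaryingFitter` (test-only dependency) to 1e-6; the
  concordance curve against an explicit double-loop pairwise count,
  exactly.
- **Parameter recovery** runs the generator with a null hazard and no
  BMI missingness: event-driven truncation of screening histories
  depends on the latent trajectory, so it is informative dropout that
  would bias *any* likelihood fit ignoring it; the recovery experiment
  is designed to test the estimator under its own sampling assumptions.
  20 replicates at 2000 women; every parameter within 3 Monte-Carlo SEs.
- **Qualitative reproduction** runs 20 replicates at 5000 women with
  discretized readings and latent-density-driven hazard, comparing the
  continuous longitudinal model's ΔLR-χ² with the BI-RADS factor
  model's, and the two measures' instability fractions. At this scale a
  cohort carries on the order of 120 events, so the ΔLR comparison —
  an expected margin of a few χ² units against a per-replicate spread
  of similar size — is near the edge of what ~120 events can resolve;
  the stability comparison has a much larger margin. Problem sizes were
  chosen to keep a full run at laptop scale (minutes, one core).

## Known limitations

- BI-RADS is modelled as continuous Gaussian; no ordinal-probit
  variant. Discretization attenuates variance components (the fitted
  σ² absorbs rounding noise); gradients keep their sign and ordering.
- The bootstrap comparison resamples women, not intervals; no IPCW
  correction is applied to the concordance, so it is a rank summary
  under the observed censoring pattern, not a censoring-free estimand.
- Absolute risk (baseline hazard) is not estimated.
- The stability analysis uses the time-varying fits from the same
  cohort; coefficient uncertainty is not propagated into the stable
  fraction.
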