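# longdens

**Longitudinal mammographic density from serial BI-RADS readings, and
its predictive value for invasive breast cancer.**

Radiologist-assigned BI-RADS breast density (A–D, here coded 1–4) is a
strong breast-cancer risk factor, but a single reading is noisy: a
woman's category often flips between consecutive screens, which is a
problem for any screening programme that assigns supplemental imaging
or risk consultations by density. `longdens` implements a *longitudinal
density* measure that smooths a woman's entire reading history through
a linear mixed model, and the evaluation machinery to ask how much
predictive information the smoothed measure carries.

The package is aimed at biostatisticians and screening-programme
modellers. Since individual-level screening cohorts are access
restricted, it ships a first-class synthetic-cohort generator with
known truth, so every method can be exercised and stress-tested end to
end.

## The model

Readings follow a linear mixed model on age and BMI,

    y_ij = x_ij' β + z_ij' b_i + ε_ij,      b_i ~ N(0, G),  ε_ij ~ N(0, σ²),

with `x = (1, a, a², a³, a⁴, bmi, a·bmi)`, `a` = age in 5-year units
(centred), and `z = (1, a)` — a random intercept and age slope per
woman with unstructured covariance `G`, fitted by maximum likelihood
with cluster-robust standard errors. The longitudinal density at a
woman's k-th screen is the empirical-Bayes (BLUP) prediction

    d_ik = x_ik' β + z_ik' Ĝ Z' V⁻¹ (y_i − X_i β)     (screens 1..k),

which equals the population age–BMI surface for a woman with no
history and shrinks toward her own trajectory as readings accrue. An
eight-category version is derived by quantile-matching baseline
estimates to the baseline BI-RADS distribution.

Predictive value is assessed with counting-process Cox models
(covariates updated at each screen, entry 6 months after baseline):
BI-RADS as a factor (3 df), continuous longitudinal density with a
quadratic (2 df), and the eight-category measure (7 df), each against
an age+BMI-only reduced model via the likelihood-ratio gain ΔLR-χ²;
plus a yearly at-risk concordance curve (yC) with cluster bootstrap,
and a stability analysis counting women whose normalised relative risk
leaves [4/5, 5/4] between their second and third mammogram.

## Worked example

```python
import longdens as ld
from longdens.pipeline import preprocess

cohort, truth = ld.simulate_cohort(ld.SimConfig(n_women=2000, seed=7))
cohort = preprocess(cohort)                     # eligibility, BMI imputation
res = ld.DensityMixedModel(cohort).fit()        # ML mixed-model fit
est = res.sequential_estimates()                # per-screen EB density
mset = ld.density_models(cohort, est)           # the three Cox models
print(mset.lr_table())
```

which prints (seed 7, 1999 eligible women, 48 events):

```
          model   delta_lr  df
0        birads  14.165623   3
1    continuous  13.039006   2
2  categorical8  20.417614   7
```

i.e. on this single small cohort the continuous longitudinal model and
the BI-RADS factor model extract comparable information beyond age and
BMI — at 48 events the two are statistically indistinguishable; the
acceptance script below runs the comparison properly, across 20
replicates of 5000 women. `res.summary()` shows the fitted fixed
effects with robust standard errors, and
`mset.continuous.summary()` the hazard-ratio table of any model.

The same pipeline is scriptable from the shell:

```bash
longdens simulate --config run.yaml
longdens fit      --config run.yaml
longdens predict  --config run.yaml
longdens evaluate --config run.yaml
longdens report   --config run.yaml
```

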