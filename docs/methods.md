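# Methods

## Problem and approach

`ckdcra` estimates how much of the chronic kidney disease (CKD) case burden in
the Chinese adult population is attributable to modifiable risk factors, and
how that attributable burden evolves over 1991–2011 and is projected to evolve
to 2031.  It follows the comparative risk assessment (CRA) framework: for each
factor, the observed exposure distribution is compared with a counterfactual
theoretical-minimum-risk exposure distribution (TMRED), yielding a
population-attributable fraction (PAF) that is multiplied by the total CKD
case count.

Seven factors are covered: systolic and diastolic blood pressure (SBP, DBP),
body-mass index (BMI) and smoking, observed longitudinally over eight survey
waves (1991, 1993, 1997, 2000, 2004, 2006, 2009, 2011), plus a blood panel —
triglycerides (TG), HDL cholesterol and plasma glucose — measured in a single
wave (2009) and carried forward to the 2011 burden estimate.

The real survey microdata (the China Health and Nutrition Survey) require
registration, so the pipeline ships with a first-class synthetic-data module
that generates an open cohort with the statistical structure the analysis
relies on, calibrated by default to the published subgroup trajectories.

## Attribution model

**Categorical exposures** (smoking in three classes never/former/current;
TG > 1.7 mmol/L; glucose > 5.6 mmol/L; HDL-C below the sex-specific threshold,
0.9 mmol/L for women and 1.1 mmol/L for men) use the multi-category Levin
formula

    PAF = Σᵢ Pᵢ(RRᵢ − 1) / (Σᵢ Pᵢ(RRᵢ − 1) + 1)

with Pᵢ the census-standardized category fractions.  Former smokers carry the
ever-smoking relative risk (1.27); a two-category mode (current vs never) is
selectable.

**Continuous exposures** (SBP, DBP, BMI) use the integral form

    PAF = (∫ RR(x) P₁(x) dx − ∫ RR(x) P₂(x) dx) / ∫ RR(x) P₁(x) dx

where P₁ is the **full standardized empirical sample**, not a summary mean:
because RR(x) is convex, a mean-based computation would understate the PAF by
Jensen's inequality.  The factual integral is therefore an exact weighted sum;
the counterfactual P₂ is a normal at the TMRED mean and SD (BMI 21 (1) kg/m²,
SBP 115 (6) mm Hg, DBP 75 (6) mm Hg), truncated below at zero and above at
m = the maximum observed exposure, the same truncation applied to both
integrals.  The counterfactual integral splits into the closed-form mass below
the TMRED mean (where RR ≡ 1) plus adaptive quadrature above it; for
Monte-Carlo draws a 200-node Gauss–Legendre grid vectorized over the drawn RR
values is used instead, and the two integrators agree to 1e-8 in tests.

Per-unit relative risks compound exponentially (log-linear dose-response),
RR(x) = rr^((x − tmred)/unit) — the standard reading of "per 10 mm Hg
increase"; linear compounding is rejected because it breaks multiplicativity.
RR is floored at 1 below the TMRED mean: the TMRED is the minimum-risk level
and no protective extrapolation is applied.  An alternative reading of the
printed "TMRED (SD)" — sampling TMRED-location uncertainty rather than using
the SD as the counterfactual spread — was considered and rejected: the
integral formula explicitly requires a counterfactual *distribution* P₂.

**Case counts.**  Total CKD cases = prevalence × adult census population
(0.108 × 846,662,309 ≈ 91.44 million), kept unrounded internally.
Attributable cases = PAF × total.  Per the published convention, the 2011
total is applied to every wave's PAF in the retrospective series and to all
projection years; this ignores ageing and population growth (overstating the
early burden and understating the future one) and is retained deliberately
for comparability.  Attributable cases of different factors overlap and are
never summed.

**Uncertainty.**  95% intervals are seeded Monte-Carlo percentile intervals:
log RR ~ Normal(log rr, (log hi − log lo)/3.92) per category or increment,
and CKD prevalence ~ Normal on the logit scale matched to its CI
(10.8%, 10.2–11.3%).  RR and prevalence draws are independent (no correlation
information is available), and the point estimate always uses the point
inputs, never the draw mean.  Exposure-sampling uncertainty is not propagated
into these intervals; a coverage simulation in the test suite confirms the
resulting intervals cover a known generative PAF in ≳90% of replicates.

## Standardization and trend testing

All exposure summaries are directly standardized to the 2010 census over the
16 joint strata of age group (18–39, 40–59, 60–69, ≥70) × sex × urban/rural
residence, using age at the survey wave.  The standardized mean is
Σ_s W_s m_s with delta-method SE; the standardized sample assigns each
observation weight W_s/n_s so its weighted mean equals the standardized mean
exactly.  A census stratum with positive weight but no observations is a hard
error — silent renormalization would hide coverage failures.  Missing
exposure values are dropped per factor and wave (complete case); no
imputation is attempted.

Covariate-adjusted wave means and the trend test use fixed-effects least
squares rather than a general linear mixed model: the mixed model is replaced
because its random-effects structure is not fully specifiable from the
available description, whereas OLS with cluster-robust standard errors by
person id (t reference with G−1 degrees of freedom) is deterministic and
testable.  The trend test enters calendar year as a numeric ("scored")
regressor, adjusting for age, sex, residence, education, occupation and
province (constant covariates are dropped within subgroups); for smoking it
is a linear-probability model on the current-smoking indicator, matching the
percentage scale of the trajectory tables.  The replacement is validated by
simulation, not by matching published p-values: under a clustered null its
type-I error at α = 0.05 stays within [0.03, 0.07] over 1000 replicates.

## Projection

The "random-effects model within each stratum among participants with ≥3
surveys" is implemented as the two-stage DerSimonian–Laird estimator: an OLS
slope per individual, then an inverse-variance-weighted stratum mean with a
method-of-moments between-individual variance component.  It is fully
specifiable, deterministic, and swappable for a likelihood-based mixed model.
For the binary smoking indicator the per-individual residual variances are
degenerate (most individual trajectories are constant, variance 0, which
makes inverse-variance weights collapse onto never-changers and bias the
slope toward zero), so binary factors use the unweighted mean of individual
slopes with its empirical SE.

Projections anchor at the last observed standardized mean (2011) rather than
the fitted intercept, so the projected series continues the observed one.
The overall slope is the census-weighted combination of the 16 stratum
slopes.  For continuous factors the 2011 standardized distribution is
location-shifted to the projected mean (shape and variance preserved) and fed
back through the PAF integral; smoking is projected on the prevalence scale
with clipping to [0, 1] (former-smoker share held at its 2011 level, the
never class absorbing the change).  Ages are not advanced during projection.

## Synthetic cohort: what it emulates, and what it does not

The generator produces an open cohort: staggered entry (45% at the first
wave, the rest spread over later waves), absorbing dropout (retention 0.85
per wave), so a realistic majority of individuals complete ≥3 waves.
Each individual's continuous exposure is

    x(t) = baseline[stratum] + slope[stratum]·(t − 1991) + b₀ + b₁·(t − 1991) + ε

with person-level random intercepts/slopes and per-wave noise (defaults: SBP
10/0.15/8, DBP 7/0.10/6, BMI 2.8/0.04/1.0 in units of
intercept-SD / slope-SD / within-SD).  Smoking is a per-stratum-per-wave
multinomial with monotone individual transitions: current smokers may quit
(current → former) with the hazard implied by the declining prevalence path;
re-uptake and late initiation are excluded.  TG and glucose are lognormal,
HDL-C normal per sex; their threshold-exceedance fractions are configurable
and default to the values implied by the published attributable fractions
(TG > 1.7: 25%; glucose > 5.6: 4%; low HDL-C ≈ 13%) — the glucose spread is
therefore narrower than a typical population fasting-glucose distribution.
SBP > DBP is enforced by clipping DBP at SBP − 1 (≈0.5% of rows at default
noise); BMI is floored at 12.

**Calibration.**  Default stratum baselines and slopes are additive in the
published subgroup deviations and shifted so the census-standardized overall
series is exact in expectation: SBP 115 → 125 mm Hg, DBP 74 → 79 mm Hg, BMI
21.67 → 23.92 kg/m² over 1991–2011.  Joint smoking prevalences are raked
(iterative proportional fitting) to the published subgroup percentages wave
by wave.  The published subgroup tables are not mutually consistent under
census weights (they were tabulated on the survey sample, e.g. the
census-weighted 2011 subgroup SBP means imply ≈121 mm Hg while the
standardized overall series prints 125), so a priority is fixed once: the
overall standardized series is matched exactly for continuous factors, and
the sex-specific smoking series is matched exactly (male current smoking
66.7% → 52.7%), letting the overall smoking level emerge (≈36% → 28%).

**Ageing design.**  Trajectories carry the *entry* stratum's baseline while
ages advance for record-keeping (standardization always uses age at wave).
Individual trajectories are therefore exactly linear and fitted slopes
estimate the calendar-period trend — the quantity the projection
extrapolates.  The cost is a mild attenuation of late-wave standardized
levels (≈1–2 mm Hg for SBP by 2011) because survivors age across stratum
boundaries carrying their entry baselines.  The alternative — re-basing
individuals to their current stratum each wave — would make the standardized
series exact but inject boundary jumps that inflate fitted individual slopes
by roughly 40%, which is the worse artefact for a projection pipeline.

Features of real survey data **not** emulated: household cluster sampling and
survey weights, province-level heterogeneity (provinces are exchangeable
labels unless a confounding switch is enabled), measurement error and digit
preference, re-uptake of smoking, mortality and CKD onset at the individual
level, and correlation between the blood panel and blood pressure/BMI.
Passing tests therefore demonstrate the estimators' correctness and the
pipeline's qualitative reproduction of the published trajectories, not
fidelity to the real microdata — the published PAF point estimates themselves
depend on the real exposure distributions and are reproduced only in sign and
magnitude.

## Numerical choices and degenerate inputs

- Per-individual slope variances are floored at 1e-12 before
  inverse-variance weighting; noise-free data thus recover the common slope
  exactly with zero between-variance.
- Strata with no variance contribution (single observation) contribute zero
  to the standardized SE rather than NaN.
- Zero-width RR or prevalence CIs collapse the Monte-Carlo intervals onto the
  point estimate exactly.
- Non-positive PAFs (exposure better than the counterfactual) are legal
  outputs, flagged by a warning in the pipeline log.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; repeated runs are byte-identical, verified via
  SHA-256 digests in the run manifest.
- Default problem sizes: 12,000 individuals in the pipeline default, 20,000
  in the acceptance script, 2,000 Monte-Carlo draws (1,000 in the script);
  simulation-based tests use 100–1,000 replicates at reduced n.  These sizes
  keep standardization Monte-Carlo error well below the effects of interest
  (SE of the standardized SBP mean ≈ 0.3 mm Hg at n = 4,000 per wave).

## Known limitations

- The trend test is a working replacement for the original mixed model; its
  p-values are calibrated by simulation but will not numerically match a
  SAS PROC MIXED fit.
- Attributable-case intervals ignore exposure-sampling variability and
  RR–prevalence correlation.
- The fixed-2011-total convention makes the retrospective and projected case
  series counterfactual accounting devices, not demographic forecasts.
- Location-shift projection preserves the 2011 distribution shape; a real
  secular trend may also change spread and skew.
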