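# Methods

## Pressure derivation

ePASP is the sum of the tricuspid pressure gradient and the estimated right
atrial pressure, `ePASP = 4·TRV² + RAP`, with TRV in m/s and pressures in
mmHg. RAP takes only the three guideline values {3, 8, 15} mmHg, decided by
the IVC diameter (≤ 21 mm) and sniff-test collapse (> 50 %); both boundary
cases fall into the intermediate 8 mmHg class because the low- and high-RAP
rules use strict inequalities on both axes. All cutoffs in the package
(ePASP > 40, FS < 29 %, RVEDD > 42 mm, TRV > 3.0 / 3.4 m/s) are strict
exactly as conventionally written.

One internal quirk is preserved deliberately: a primary case requires
ePASP > 40 mmHg, which with the minimum RAP of 3 mmHg corresponds to a
gradient > 37 mmHg, yet the RAP-missing fallback criterion is
gradient > 36 mmHg (TRV > 3.0 m/s). The fallback is implemented as stated,
so the fallback path is very slightly more permissive than the full-data
path.

## Case ascertainment

Each participant follows a four-step hierarchy: (1) ePASP measurable →
case iff > 40 mmHg; (2) TRV measured but RAP missing → case iff gradient
> 36 mmHg; (3) jet absent or too small to measure → assumed non-case
(such jets overwhelmingly indicate normal pulmonary pressures); (4) no
tricuspid data recorded → excluded. The stringent definition repeats the
hierarchy at 50 mmHg / TRV 3.4 m/s; the RV-augmented definition adds
dilated-RV participants as cases and can classify participants who have an
RV measurement but no tricuspid data, so its denominator may exceed the
primary one. By construction stringent ⊆ primary ⊆ RV-augmented case sets.

## Diastolic staging

The three-level staging (normal or stage 1 / pseudonormal stage 2 /
restrictive stages 3–4) is a configurable decision table
(`ephstudy.config.DiastolicThresholds`). Defaults: E/A windows at 0.75 and
1.5; raised filling pressure when E/E' ≥ 10 or E' < 8 cm/s; in atrial
fibrillation the E/A axis is replaced by the E-wave deceleration time with
a 140 ms restrictive cutoff, and the A-wave is never read. Isolated
impaired relaxation (E/A ≤ 0.75) and tall-E/A patterns with normal filling
pressure both grade as normal-or-stage-1. These cutoffs are an
implementation choice in the range used by the elderly-cohort staging
literature; every test references this default table, not any external
source, and the table is swappable via YAML.

## Prevalence statistics

Prevalences are binomial proportions over the non-excluded denominator with
plain Wald 95 % intervals (no continuity correction), truncated to [0, 1].
Percent display uses half-up rounding to one decimal so printed triples are
bit-reproducible. Between-group comparisons default to Pearson chi-square
for categorical characteristics (one omnibus p across levels) and Welch's
t for continuous ones — conventional defaults, swappable in code. Wald
intervals at p ≈ 2.6 %, n ≈ 2800 are mildly anti-conservative (empirical
coverage ≈ 94 %); this is a property of the interval, verified in the
acceptance suite.

## Missing data and models

Smoking and COPD first receive last-observation-carried-forward from the
prior visit. Remaining incomplete covariates (each capped at 6 % missing)
are multiply imputed (m = 5) by chained equations with predictive mean
matching: Bayesian parameter draws, k = 5 donors, 10 sweeps. PMM copies
observed donor values, so categorical covariates never receive invalid
codes. TRV, RAP, RVEDD and the outcome ePASP inform the imputation
regressions as predictors but are never imputed; where they are missing
they enter mean-filled with a missingness indicator. The engine choice
matters little at this missingness level: the pooled-coefficient estimand
is engine-agnostic, which the zero-missingness degenerate case pins down
exactly (impute → fit → pool equals a single OLS to machine precision).

Model A regresses ePASP on one factor at a time plus age and sex (age's own
fit adjusts for sex only, and vice versa), restricted to participants with
estimable ePASP; the outcome is never imputed. Model B enters every factor
with pooled Model-A p < 0.05 (strict, on the unrounded p; multi-level
factors use a pooled multi-parameter Wald test) simultaneously. Pooling
follows Rubin's rules with Barnard–Rubin degrees of freedom. Effects are
reported per 10 years of age, per 5 kg/m² of BMI and per 10 % of fractional
shortening; internal fits are on raw scales with deterministic rescaling.

Because selection into Model B conditions on statistical significance,
factors whose true effect is near the selection boundary (e.g. a 0.3 mmHg
diabetes effect) show winner's-curse inflation *conditional on being
selected*; strongly associated factors are unaffected. This is a property
of the two-step design itself, not of the implementation.

## Synthetic cohort generator

The generator is the package's test bed: it emulates an elderly
population-based echo cohort and carries exact ground truth.

- **Covariates.** Age is truncated normal with a floor at 65 years; the
  configured mean/SD (76.4 / 6.2) describe the *realised* truncated
  marginal, and the parent distribution is solved numerically. Women 59 %,
  BMI 27.2 (4.0) kg/m², smoking never/former/current 35.3 / 55.5 / 9.2 %,
  COPD 10.4 %, diabetes 12.8 %, systemic hypertension 87.1 %, diastolic
  stages 61.5 / 35.0 / 3.5 %, FS 41.1 (5.9) %, RVEDD 33.0 (4.4) mm, atrial
  fibrillation 8 %. A small Gaussian copula induces age–COPD (ρ = 0.20),
  age–diastolic-stage (0.30) and BMI–hypertension (0.25) correlations; the
  real joint distribution is unpublished, so these are calibration choices
  that make the expected subgroup gradients (older bands, COPD, LV
  dysfunction) emerge qualitatively.
- **Outcome first, echo second.** True ePASP is generated from the linear
  predictor over these covariates (default effect vector: 2.2 mmHg per
  10 years, −0.6 women, 0.7 per 5 kg/m², −0.5 per 10 % FS, 1.1 stage 2,
  7.1 stages 3–4, 2.4 COPD, 0.3 diabetes, 1.3 hypertension) plus a
  zero-mean, slightly right-skewed log-normal residual. RAP is drawn from
  {3, 8, 15} with probabilities (0.85, 0.13, 0.02) — giving the
  characteristic 3.9 (2.3) mmHg marginal — and TRV is back-derived as
  √((ePASP − RAP)/4), flooring ePASP at RAP in the rare draw below it
  (≈ 10⁻³ of rows, logged). IVC, mitral-inflow and LV/RV dimensions are
  emitted inside the decision windows of the assigned RAP category, stage
  and FS, so the derivation stage recovers all truth exactly; this makes
  parameter-recovery tests well-posed.
- **Calibration.** Three free parameters — intercept 5.4950 mmHg, residual
  SD 6.5425 mmHg, log-scale skew 0.1133 — were solved once (root-finding at
  n = 300,000 with common random numbers) so a default cohort jointly
  reproduces mean estimable ePASP 26.3 mmHg, SD 7.0 mmHg and a 2.6 %
  primary-definition prevalence, then frozen. A 10⁶-row check gives
  26.30 / 7.00 / 2.59 %.
- **Missingness.** 16.5 % of participants form an excluded stratum with no
  tricuspid data (IVC and RV measurements partially retained). Among the
  rest, the jet is unmeasurable with probability `expit(a − 0.05·ePASP)`,
  the intercept solved per cohort so the overall rate is 23.7 % — low
  pressures make the jet harder to measure, a moderate steepness chosen so
  the masked/unmasked separation is clear (≈ 1.3 mmHg in true ePASP) while
  the estimable-subset regression estimand stays within sampling error of
  the generating coefficients. RAP (IVC) is missing completely at random
  at 9.7 %; covariates at their small per-variable rates (0.4–4 %);
  smoking/COPD at 3 % with prior-visit values available for LOCF (10 % of
  priors themselves missing, so a residue enters imputation).

**What the generator does not emulate:** measurement error in the echo
readings (truth is recovered exactly), clinical PH aetiologies and
medication effects, longitudinal trajectories beyond one prior visit, and
any covariate dependence of the *excluded* stratum (it is MCAR here,
whereas real excluded populations differ systematically). Passing tests
therefore demonstrate correctness of the derivation/classification/
inference machinery under the assumed data-generating model, not the
field validity of echo-based PH screening.

## Problem sizes and numerics

The acceptance harness uses n = 20,000 for coefficient recovery (pooled
SEs ≈ 0.05–0.35 mmHg) and n = 100,000 for distributional calibration;
both run in seconds. Wald intervals use z = Φ⁻¹(0.975) = 1.959964. PMM
ties are broken by random donor choice within the k-nearest window; all
RNGs are `numpy` Generators seeded explicitly, and generation, masking and
imputation use separate derived seeds so stages are independently
reproducible. Degenerate inputs are handled explicitly: missing inputs
propagate as missing (never sentinel numbers), physically impossible LV
diameters raise, empty subgroup levels warn and are omitted, and an empty
Model-B selection raises rather than silently fitting an intercept-only
model.
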