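# Methods

`cpree` implements the statistical workflow for assessing resting energy
expenditure (REE) in children with severe (GMFCS level V) spastic
quadriplegic cerebral palsy: prediction-formula evaluation, indirect
calorimetry processing, method-comparison statistics, development and
validation of a population-specific model, and its clinical nomogram.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic data do and do not establish.

## Prediction formulas

The standard equations (WHO, Schofield weight, Schofield weight & height,
Harris-Benedict, Oxford, Mifflin-St Jeor) are evaluated exactly as tabulated
for clinical use, with two population-specific equations alongside:

    CP_PRELIMINARY:  REE = 24·W + 380                      (kcal/day, W in kg)
    CP_FINAL:        REE = 28.43·W − 17·TSF + 398.2        (TSF in mm)

Conventions enforced in code:

* **Age bands are half-open** — [0,3), [3,10), [10,18), [18,30) — so exactly
  10.0 years dispatches to the 10–18 equation; 30 y and above raises for the
  banded formulas.  Harris-Benedict and Mifflin are not banded.
* **Height units differ by formula**: Schofield weight & height takes metres
  (its height coefficients are on the metre scale); Harris-Benedict and
  Mifflin take centimetres.  All stored heights are centimetres; conversion
  happens inside each evaluator.
* The widely reprinted Schofield weight & height male <3 y weight
  coefficient "1.67" is a transcription slip for 0.167 (1.67 gives absurd
  REE at infant weights); 0.167 is the default, and `as_printed=True`
  evaluates the reprinted value for comparison.

## Indirect calorimetry

Steady state is the earliest window of at least 5 minutes in which the
coefficient of variation (SD/mean, sample SD) is below 5% for the
respiratory quotient and below 10% for VO2 and minute ventilation.  CV is
the conventional metabolic-cart criterion; "variation" is not otherwise
standardised, so the choice is documented here.  The window slides breath by
breath and the earliest qualifying window wins, deterministically.  REE over
the measurement period (default 20 min after onset) uses the abbreviated
Weir equation without the urinary-nitrogen term,

    REE (kcal/day) = 1.44 · (3.941·VO2 + 1.106·VCO2),   VO2/VCO2 in ml/min.

## Method comparison

With D = formula − calorimetry and A = the pair average, the classic
Bland-Altman limits are mean(D) ± 1.96·SD(D); proportional bias is declared
when the Pearson correlation of D on A has two-sided p < 0.05.  Under
proportional bias the difference is regressed on the average
(D = a + b·A + e, residual SD τ with the n−2 denominator), giving sloped
limits of agreement a + b·A ± 2τ (multiplier exactly 2 on this path) and the
bidirectional conversion equations

    y1|y2 = a/(1−b/2) + (1+b/2)/(1−b/2)·y2 ± 2τ/(1−b/2)
    y2|y1 = −a/(1+b/2) + (1−b/2)/(1+b/2)·y1 ± 2τ/(1+b/2),

whose point predictions are exact mutual inverses for |b| < 2.  Lin's
concordance correlation coefficient uses population (1/n) moments — the
(n−1)/n convention moves the third decimal at small n, which the brute-force
oracle tests pin down — with a Fisher-z confidence interval using Lin's
asymptotic standard error.

## Model development and validation

* **Nonlinearity.** Weight is tested with a 3-knot restricted cubic spline,
  knots at the 0.10/0.50/0.90 quantiles (Harrell's 3-knot default), basis
  normalised by (t3−t1)²; the likelihood-ratio test uses the Gaussian
  likelihood (the models are least-squares fits), df = 1.
* **Selection.** Limited backward selection starts from weight (forced) plus
  height, age, sex (male = 1), TSF, and removes the worst non-forced term
  while its partial-F p-value exceeds 0.05; an AIC criterion is available
  behind a flag.
* **Fit indices.** R²adj = 1 − (1−R²)(n−1)/(n−p−1); MSE = SSE/n ("mean
  squared error of the estimate"); the residual SD separately uses n−p−1.
  Both are reported to avoid denominator ambiguity.
* **Optimism correction** (Harrell): for each of 3,000 bootstrap resamples
  of size n the model is refitted; training = mean apparent index on
  resamples, test = mean index of resample models evaluated on the original
  data, optimism = training − test, corrected = original − optimism.  The
  two identities hold exactly by construction, for MSE as well — the MSE
  optimism is typically negative, so the corrected MSE exceeds the apparent
  one.  Rank-deficient resamples are skipped and counted.
* **Train/test split.** The first 54 subjects in cohort order are the
  training set (the split is historical, not random); an optional seeded
  shuffle is available.  Test-set concordance (Lin's CCC) is compared across
  all formulas plus the new model.
* **Group comparison.** Nutrition groups are z ≤ −2 (moderate + severe
  malnutrition) vs z ≥ −1; scores in the open gap (−2, −1) are left
  unassigned and dropped from comparisons rather than forced into a group.
  Quantile differences at τ = 0.25/0.50/0.75 use type-7 sample quantiles
  (the difference-of-sample-quantiles estimator coincides with
  group-indicator quantile regression); 95% CIs come from a stratified
  nonparametric bootstrap resampling subjects within each group, which keeps
  both groups populated in every replicate.
* **Intake model.** REE ~ caloric intake + age on complete cases, with sex
  included and dropped when not evident (p > 0.05); effects are also
  reported per +388 kcal/day of intake and per +4.75 years (+1 SD) of age,
  the clinically quoted scalings.

## Nomogram

Each predictor axis maps its value to points
|β_j|·(x − x_ref)/max_k(|β_k|·range_k)·100, with x_ref the range end that
minimises the term (the maximum for the negative TSF coefficient, so TSF
points fall as skinfold rises); the dominant predictor spans exactly 0–100
points and the total-points axis is the linear map back to kcal/day.
Reading the nomogram is algebraically identical to evaluating the model
(round-trip error < 1e-6 kcal/day, tested over 1,000 random inputs).
Default ranges are weight 5–60 kg and TSF 2–20 mm — the cohort's
interquartile spans with clinical margin, declared defaults rather than
reproductions of any published axis.  Values outside the ranges are refused
rather than extrapolated.  The plain-text tick table is the canonical
rendering surface; the SVG figure is a thin layer over it.

## Synthetic cohort generator

No subject-level data are deposited, so the generator emulates the published
population description: n = 100, 65% male, median [IQR] weight
19.45 [14.43, 26.05] kg, TSF 7.70 [5.40, 9.20] mm, age 9 [6, 14] y, height
118 [107.55, 135.25] cm, arm circumference 18 [15.2, 20] cm, median RQ
0.7144.

* **Marginals** are split log-normal: a standard-normal deviate is mapped
  through a two-slope log-linear transform anchored at the configured
  quartiles, so the median and both quartiles are matched exactly while each
  tail remains log-normal.  (A single-sigma log-normal can only match the
  quartile ratio and misses asymmetric quartiles such as TSF's by ~9%.)
* **Dependence** is a Gaussian copula.  Only the weight–TSF rank correlation
  (default Spearman 0.3) is a configured knob; the remaining entries
  (weight–height 0.85, weight–age 0.75, height–age 0.85, …) are fixed
  physiological realism, not claims about the study sample.
* **REE** = 398.2 + 28.43·weight − 17·TSF + noise with residual SD
  200 kcal/day (the square root of the reported test-set MSE, ≈√40,164),
  floored at 250 kcal/day.  The floor binds for ~1.5% of subjects and
  attenuates the fitted TSF coefficient by ≈0.3 kcal/day/mm at very large n —
  well inside Monte-Carlo error at the n = 5,000 used for recovery checks.
* **Caloric intake** is constructed for exact expected recovery of the
  intake model: the REE noise is decomposed into an intake-borne component
  (slope × an intake-specific normal deviate, SD 250 kcal/day) plus an
  independent remainder, and intake carries the full weight/TSF structural
  signal divided by the intake slope (163/388 kcal REE per kcal intake) plus
  a negative age term (102/4.75 kcal/day per year).  Regressions of REE on
  (weight, TSF) and on (intake, age) are then both unbiased.  The cost is a
  wider intake spread than the published marginal (median matched at
  1,146 kcal/day; IQR wider than 1,000–1,411): the two constraints cannot
  hold simultaneously, and slope recovery was prioritised.
* **BMI z-scores** are anchored to the weight copula deviate
  (z = −2.1 + 1.2·z_w + 0.6·ε), targeting the reported ~52% share of
  moderate + severe malnutrition and making the better-nourished group
  systematically heavier, hence higher-REE — the qualitative group contrast
  the analysis expects.
* An optional flag injects one 209 kcal/day subject (severe-malnutrition
  z-score) to exercise the screening rule, whose default floor of
  300 kcal/day removes exactly such values.

**What passing tests show, and what they do not.**  The generator reproduces
the population's marginal summaries and the assumed linear REE structure
with Gaussian noise.  Real calorimetry residuals need not be Gaussian or
homoscedastic; real formula-vs-calorimetry biases arise from physiology, not
from construction; and the real train/test split is historical.  Green tests
therefore validate the *estimators and their implementation* (recovery,
identities, oracle agreement), not the clinical accuracy of any formula on
real children.

**Breath traces** are generated at ~20 breaths/min with an unsteady lead
(45% sinusoidal VO2 oscillation, period 1.8 min, window CV ≈ 14–24%,
safely above the 10% tolerance) followed by a stationary segment (1.5%
breath-level noise) whose mean VO2 solves the Weir identity at the requested
REE and RQ.  Detection therefore lands within ~0.5 min of the constructed
changepoint (windows overlapping the lead by more than ~0.5 min still fail
the VO2 tolerance).

## Problem sizes and determinism

Defaults chosen as the package's own analysis scale: cohort n = 100 for the
analysis scripts (matching the study size), n = 5,000 for coefficient
recovery, 3,000 bootstrap resamples for optimism correction, 2,000 for
quantile CIs, 1,000 null simulations for the LRT calibration check.  All
randomness flows from `numpy.random.default_rng` seeds; the pipeline fans a
single seed into per-stage substreams so stages can be rerun in isolation,
and repeated runs under one seed are byte-identical.

## Known limitations

* The generator encodes no feeding-mode effect on REE and no WHO z-score
  pipeline (z-scores are consumed as externally computed inputs).
* The conversion equations assume a single measurement per subject and
  method; repeated-measures limits of agreement are out of scope.
* Lin's CCC confidence intervals are asymptotic; at test-set sizes around 40
  they are approximate.
* The CP-specific equations and the nomogram apply to the GMFCS V
  population they were built for and should not be extrapolated to other
  severity levels — the nomogram enforces its declared predictor ranges for
  this reason.
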