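# Methods

`inpheld` implements the statistical core of a prognostic-evaluation study
design used in idiopathic normal pressure hydrocephalus (iNPH): patients
undergo continuous external lumbar drainage (ELD), are assessed with a
traditional battery (MMSE, 5-m timed-up-and-go, 10-m walk) and a digital
battery (five computerized cognitive tests, five camera-derived gait
parameters) before and three days after drainage, and a subgroup proceeds
to shunt surgery whose outcome the drainage-test response is meant to
predict. This note records the models, conventions and numerical choices
the package commits to.

## Scoring model

**Direction-aware z-scores.** Each digital cognitive test is standardized
against a healthy-population norm (mean μ, SD σ) so that larger z always
means better performance: z = (x − μ)/σ for higher-better scores,
z = (μ − x)/σ for times. The composite cognitive z is the unweighted mean
of the five test z-scores. In an impaired cohort the composite sits well
below zero (around −2.3 under the default simulation).

**Improvement rates.** Every pre/post pair is converted to an oriented
signed percent so that positive always means clinical improvement:
(post − pre)/pre × 100 for higher-better parameters, (pre − post)/pre × 100
for lower-better ones. Composites are unweighted means: the gait rate over
the five gait parameters, the traditional rate over MMSE/TUG/TMWT-time/
TMWT-steps, and the combined rate the (default equal-weight) mean of the
cognitive and gait rates.

**Cognitive-rate denominator.** The percent-change formula applied
literally to a *negative* baseline z flips the sign of every improvement.
Because baseline composite z is negative for essentially all patients in
this population while improvement is reported as positive, the cognitive
rate divides by |z_pre| by default; the signed-denominator form is
available as `ScoringOptions(cognitive_denominator="raw")`. Likewise MMSE
inside the continuous traditional composite uses a percent form (with
|pre| denominator) so the four components are commensurate, even though
the *binary* drainage-test rule uses the absolute 3-point MMSE criterion.

**Degenerate denominators.** |pre| ≤ ε (default ε = 1e−9) yields an
undefined rate plus a `zero_denominator` flag; composites missing a
component are undefined (flagged `missing_component`) unless the
partial-mean option is set. Undefined quantities propagate as `None`/`null`,
never as 0 or NaN.

## Outcome rules

Drainage-test positivity (all thresholds inclusive): ≥20% improvement in
10-m walk time or steps, or ≥10% in both, or ≥10% in TUG time, or ≥3 raw
MMSE points. Shunt response: a ≥1-point improvement in mRS or in any
single iNPHGS domain at the *last* follow-up versus baseline; purely
subjective improvement never qualifies, so a patient with subjective-only
gains is a nonresponder. An `any_visit` option implements the alternative
reading in which improvement at any follow-up qualifies.

## Firth penalized logistic regression

With roughly five events, plain maximum likelihood is badly biased and
diverges under separation. The package fits logistic models by maximizing
the Jeffreys-penalized likelihood ℓ(β) + ½ log det I(β), whose gradient is
the modified score Σᵢ(yᵢ − πᵢ + hᵢ(½ − πᵢ))xᵢ. Newton–Raphson with
step-halving guarantees a monotone penalized likelihood; convergence
requires the modified-score infinity norm and the step size both ≤ 1e−8
(max 100 iterations, 20 halvings). On a saturated 2×2 design the penalty
is exactly equivalent to adding ½ to each cell, which the tests use as a
closed-form oracle; under complete separation the estimates stay finite.

Default confidence intervals are Wald intervals from the inverse penalized
information (the study-style symmetric OR intervals); profile-penalized-
likelihood intervals are available and found by bisection on the ½χ²₁
drop. Models are fit on the raw percentage-point scale (no covariate
standardization) so an odds ratio reads "per 1 percentage point of
improvement"; the default adjustment set is sex and Evans index. The
outcome is coded 1 = shunt **nonresponder** — the rare, clinically
unfavorable class — which is also the ROC positive class. This coding is
forced by the arithmetic of the published operating points (a sensitivity
of 0.40 with 5 cases is only consistent with nonresponders as positives).

## Diagnostics

* **AUC** — Mann–Whitney form with half credit for ties, computed via
  midranks; verified exactly against the O(mn) pairwise definition.
* **Youden cutoff** — maximizes J = sens + spec − 1 over midpoints between
  adjacent observed scores (plus outer sentinels); ties go to the smallest
  threshold; degenerate score vectors return J = 0.
* **Score scale** — by default ROC scores are the unadjusted Firth-model
  predicted probabilities of nonresponse; `roc_mode="rate"` uses the
  sign-flipped raw rate instead. AUC is identical between the two (the
  logistic map is monotone); only the cutoff scale changes, and neither
  scale is treated as canonical.
* **DeLong test** — per-observation placement components give variances
  and the covariance of paired AUCs; identical score vectors return
  Z = 0, p = 1 by convention.
* **Bootstrap** — percentile intervals from resampling stratified within
  outcome class (with 5 positives an unstratified resample frequently
  loses the class). The whole operating-point derivation (model refit,
  cutoff selection, confusion metrics) is repeated inside each resample.
  BCa was deliberately not used: at these class sizes the acceleration
  estimate is unstable.
* **Permutation tests** — outcome labels are permuted and both nested
  Firth models refit; the statistic is the penalized likelihood-ratio
  statistic for the covariate block of interest;
  p = (#{perm ≥ obs} + 1)/(B + 1). Non-convergent refits count toward the
  numerator (conservative). An intercept-only null is fit once, since it
  depends on the permuted outcome only through its sum.
* **Calibration** — Spiegelhalter z-test, logistic recalibration
  slope/intercept of outcomes on logit(p̂) (ML Newton, Firth fallback on
  separation), and mean absolute calibration error over equal-count bins
  (default 5 bins at n≈39; undersized bins merge with a neighbor).
* **Worked-example reconstruction** — `metrics_from_rates` inverts rounded
  sensitivity/specificity at known class sizes to the unique integer
  confusion matrix (half-up rounding at the printed precision) and derives
  PPV/NPV from it; inconsistent inputs raise with the candidate sets.

Resampling defaults are 2000 bootstrap resamples and 5000 permutations; a
master seed spawns independent substreams per stage, so reports are
byte-identical across reruns with the same inputs and seed.

## Synthetic cohort generator

Patient-level data for this design are not publicly deposited, so the
generator is the package's test bed and carries its ground truth. It
emulates: 70 patients, 39 shunted, a latent 34/5 responder/nonresponder
split; baseline demographics, Evans index (log-normal around the group
medians), DESH score, symptom prevalences and all three assessment panels
anchored to the emulated population's published summary statistics; and
class-conditional distributions of the composite improvement rates
(responders centred near +5% gait improvement, nonresponders near −12%;
cognitive rates overlapping heavily; traditional rates nearly identical
across classes so the traditional battery's discrimination sits near the
~0.55 level the design assumes).

Quantities specified as median/IQR are drawn from a **two-piece normal**
whose three quartiles match the anchors exactly; mean/SD quantities use
the equivalent symmetric anchor. Cognitive and gait improvement are
coupled by a Gaussian copula with correlation 0.3 (the cohort literature
implies interdependence but quantifies none; it is a single config knob).
Post-drainage panels are **back-solved** from the sampled rates — the five
gait-parameter rates scatter around the composite with centred noise (SD 6
percentage points) so their mean equals the sampled composite exactly —
guaranteeing internal consistency between panels and rates up to the
positivity clipping of raw scales. Responders' follow-ups are drawn so at
least one scale improves measurably (unless `followup_noise` > 0);
nonresponders improve on no scale, 80% reporting subjective-only gains.

What the generator does **not** emulate: the joint distribution across all
ten parameters (unknowable from printed marginals), learning effects,
attrition, measurement error correlated over visits, and whatever joint
structure gave the original cohort its strong combined-score separation.
The printed marginal medians/IQRs imply a population combined-score AUC
near 0.70, not the headline ~0.9 observed in the real cohort; passing
tests on this generator therefore demonstrates correctness of the
machinery and directional recoverability, not the study's effect sizes.
Consequently single-cohort results at n = 39 with 5 events are highly
seed-dependent (AUC swings of ±0.2 are normal), which is itself faithful
to the design's small-sample regime.

## Problem sizes used by the test suite

Oracle-equivalence suites run 200–500 random instances; null-calibration
suites use 200 permutation replicates of B = 500 and 2000 DeLong null
simulations; parameter recovery uses 100 seeds of 500-patient cohorts;
calibration recovery uses 500 seeds at n = 2000. Bootstrap coverage is
checked at B = 400 over 120 cohorts with a wide documented band
(0.80–0.99): the percentile bootstrap for the AUC with 5 positives is
known to undercover slightly.

## Known limitations

* Norms are a required user input for real data; the shipped
  `placeholder_norms()` table is synthetic, chosen only to place the
  simulated cohort near the assumed baseline impairment (composite
  z ≈ −2.35).
* The continuous "traditional score" behind the published cutoff has no
  printed definition; the package defines it as the mean of four oriented
  traditional-test rates and treats no published cutoff value as ground
  truth.
* Profile-likelihood intervals refit the constrained model many times and
  are O(p) slower than Wald; they are opt-in.
* The pipeline analyses complete cases for the model stages (patients
  missing any composite rate are dropped from fitting, with counts
  reported); no imputation is attempted.
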