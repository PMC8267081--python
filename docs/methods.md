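# Methods

## Composites and decision rules

**Ordinal recoding.** Each validity-composite component is a multi-cutoff
band table on the instrument's native scale (raw score, age-corrected
scaled score with normative mean 10/SD 3, or T-score with mean 50/SD 10).
Bands are closed integer intervals taken verbatim from the published
cutoff tables; open ends are encoded as nulls. Two edge conventions are
deliberate:

* The processing-speed composite's coding-subtest row is implemented
  literally as printed (code 0 requires ACSS ≥ 6, code 1 is exactly 5),
  even though the printed bounds look typographically odd; verbatim bounds
  beat editorial guessing.
* The word-reading row's lowest band stops at scaled score 1, leaving a
  floor score of 0 unmapped. Scores below the lowest band extrapolate to
  the maximum code with a warning: a floor score cannot be less aberrant
  than the band above it, but the extrapolation is flagged because it goes
  beyond the published table.

Any other gap between bands raises an error rather than guessing.

**Composite scoring.** EI-5 composites sum five 0–3 codes (range 0–15);
total ≤ 1 is Pass, 2–3 Borderline, ≥ 4 Fail. Borderline profiles are
excluded from every dichotomous analysis (including AUC against a
dichotomized composite) and the exclusion count is carried through all
outputs, because it silently changes n. The default completeness policy is
`require_all`: a missing component yields an incomplete result (band NA),
never a silent zero. A `min_k` proration policy exists but is marked
non-canonical — whether the original analyses prorated incomplete
composites is not stated in the source tables, so the conservative policy
is the default. The ability composite (VPA-3) sums three 0–4 normative
band codes (range 0–12) and has no Pass/Fail banding.

**Decision rules.** The Word Choice Test fails on accuracy ≤ 47 *or*
time-to-completion ≥ 156 s; with one input missing the decision uses the
available one, and only two missing inputs give NA. The combined two-trial
recognition rule passes if *either* trial exceeds the cutoff; "above the
cutoff" is implemented as strictly greater than the ≤-style cutoff value,
consistent with the ≤-convention of the published failure bands. The TOMM
Trial-1 cutoff is a required configuration value with no canonical
default: published laboratories differ, and the bundled example value (43)
is an illustrative placeholder, not an endorsement. Below-chance detection
on the forced-choice trial is strict (< 12, the expectation of 24
two-alternative guesses). The ability criteria dichotomize at VPA-3 ≥ 5,
clock-drawing raw ≥ 8, and delayed-recall raw ≥ 8 (the raw score, not the
T-score used elsewhere).

## Accuracy engine

Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), overall accuracy =
their arithmetic mean, each reported as None when its denominator is empty
(never a division error). The sweep's BR_Fail is computed over all
scoreable records *before* criterion alignment, mirroring how failure base
rates are reported descriptively; the aligned predicted-positive rate is
available separately. On complete data the two coincide through the
identity BR_fail = BR·sens + (1−BR)·(1−spec), which is tested.

AUC is the rank/U-statistic estimator (ties ½), verified exhaustively
against brute-force pairwise comparison. Orientation (whether low or high
scores mark the positive class) is an explicit argument recorded in the
result, never inferred from the data. Confidence intervals: Hanley–McNeil
by default — closest to legacy clinical-psychometrics software output —
with DeLong available; the published tables do not name their CI
estimator, so both ship and every report labels which was used. CIs are
clipped to [0, 1].

Cutoff selection is specificity-first: the most liberal cutoff (highest
≤-cutoff, lowest ≥-cutoff) whose specificity clears the .84 floor, flagged
for whether it also clears the .90 desirable standard; ties prefer the
more liberal cutoff since it maximizes sensitivity at acceptable
specificity.

## Contrast statistics

Cohen's *d* from summary statistics uses the equal-weighted pooled SD,
`sqrt((s1² + s2²)/2)`. This is the convention that reproduces published
clinical validity-research effect sizes from their printed group
means/SDs; it differs from the n-weighted pooled form at unbalanced n, so
the choice is documented prominently. The default independent t-test is
pooled-variance Student's; a Levene (mean-centered) p < .05 attaches a
heteroscedasticity flag rather than silently switching to Welch, mirroring
footnote-style flagging in published tables (Welch is available
explicitly). The two-proportion z uses the pooled proportion; its square
equals the 2×2 Pearson chi-square without continuity correction (tested).
The paired test reports mean(diff)/sd(diff) as its effect size; degenerate
inputs (zero-variance differences, single-class proportions, zero-variance
correlates) return undefined markers instead of raising.

## Clinical banding

Recognition scores band as Invalid 0–14, Questionable 15–17, Inferior
18–19, WNL 20–22, Superior 23–24; the bands partition 0–24 exactly, and the
interpretable ability range (18–24, seven points) is exported as a
constant. One scheme serves both recognition trials; per-trial schemes are
configurable for future recalibration. Banded reports show cumulative
percentages per cohort with scores ≤ 12 aggregated into one row, plus
conditional means of auxiliary measures among examinees at each score.

## The simulator

**Model.** Latent status ~ Bernoulli(p_noncredible); three ability factors
(memory, processing speed, visual-perceptual) are standard normal with a
common 0.5 inter-factor correlation (the true joint structure among all
component instruments is unpublished; 0.5 is an implementer choice in the
typical range for cognitive batteries). Each instrument is
`intercept + slope·(factor − status·δ_domain·mult) + ε`, then rounded on
integer scales and clamped to the instrument range (clamped fractions are
recorded for ceiling diagnostics). Suppression is additive in latent space
before discretization — the simplest mechanism that lowers means and, in a
mixture, inflates the variance of failing groups. Domain-level suppression
is larger for memory (δ = 1.0) than for speed/visual domains (0.8),
emulating modality specificity; instrument-level multipliers fine-tune the
native-scale shift.

**Presets.** `clinical_2021` (n = 52, p_noncredible = .404) and
`student_2021` (n = 83, p_noncredible = .09) were calibrated once by
iterative moment matching at n = 400 000 against the published group
summaries: recognition-trial means/SDs (19.3/2.9 and 19.3/2.2 clinical;
22.1/1.8 and 21.3/1.6 student), the between-trial correlations (.37
clinical, .62 student), the TOMM Trial-1 failure base rates (41.5% / 9.0%
at the example cutoff), the joint Word Choice failure rates (45.3% /
29.3%) and the code-0 (pass) base rate of every validity-composite
component. The fitted parameters ship as data in `pvcalib.simulate`. The
student preset reproduces the anomalously high word-choice failure rate as
a marginal property without modeling its cause. Missingness is
per-instrument completely-at-random, set to the attendance-driven rates of
the emulated samples (about 19% for TOMM, 10% for WCT among students;
2–2.5% for clinical battery components).

**What the simulator does not emulate.** Scores are discretized Gaussians:
real distributions are skewed with hard ceilings and occasional outliers;
suppression in real malingering is strategic and item-dependent, not a
constant latent shift; missingness is not random in real referrals; and
the full cross-correlation matrix among instruments is invented beyond the
moments listed above. Passing calibration tests therefore shows the
pipeline recovers the *published moments and its own generative truth* —
it does not certify classification-accuracy tables for real patients,
which require raw clinical data.

## Numerical and testing choices

Monte-Carlo test sizes were chosen to keep the whole suite fast while
leaving comfortable margins: calibration checks run at n = 5000 (standard
errors: ~0.04 points on a recognition mean, ~0.014 on a correlation,
~0.7 percentage points on a base rate) against tolerances of 0.15, 0.05
and 3–5 points respectively; oracle-equivalence checks compare an
n = 5000 pipeline estimate with a 10⁶-draw oracle at ±0.03. Property
suites (AUC vs brute force, recoding monotonicity over every in-range
integer, band partition, sweep monotonicity, z²=χ² identity) are
exhaustive or derandomized. Report CSVs are byte-identical across reruns
at a fixed seed.

## Known limitations

* Printed t statistics that depend on unrounded raw data are not
  reproducible from summary statistics and are not targeted.
* The clinical sample size in the emulated study is internally
  inconsistent (52 vs 53 in different tables); the data model imposes no
  fixed n and the presets use 52.
* The paired-contrast effect size convention in the emulated study is
  ambiguous (its printed value matches t/√n, not the summary-statistic
  formulas); this package reports mean(diff)/sd(diff) and documents the
  choice.
* AUC CIs can differ from published values computed with other estimators;
  both shipped methods are labeled in output.
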