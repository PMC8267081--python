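# pvcalib

Calibration and evaluation of **performance-validity decision rules** for
neuropsychological test batteries.

## The problem

Clinical decisions from neuropsychological testing assume the examinee gave
credible effort. Performance validity tests (PVTs) and embedded validity
indicators (EVIs) detect non-credible responding by dichotomizing scores at
published cutoffs; calibrating such a cutoff means sweeping candidate
thresholds and characterizing each by its failure base rate
(BR<sub>Fail</sub>), sensitivity, specificity and AUC against criterion
measures, under a *specificity-first* policy (minimum acceptable specificity
.84, desirable ≥ .90 — a false accusation of non-credible performance is
costlier than a miss).

`pvcalib` implements that workflow for batteries built around the Rey
Complex Figure Test (RCFT) recognition trials — the 24-item Yes/No
Recognition trial and the 24-item two-alternative Forced Choice Recognition
(FCR) trial — together with:

* **Ordinal validity composites (EI-5).** Five validity indicators are each
  recoded onto a 0–3 ordinal scale (0 = passes the most liberal published
  cutoff, 3 = fails the most conservative), then summed to a 0–15 composite:
  total ≤ 1 ⇒ *Pass*, 2–3 ⇒ *Borderline* (excluded from dichotomous
  analyses), ≥ 4 ⇒ *Fail*. Two built-in variants cover the memory and
  processing-speed domains.
* **An ability composite (VPA-3).** Three visual-perceptual tests recoded
  onto normative five-point bands (0 = Impaired … 4 = Very Superior) and
  summed to a 0–12 scale, used as a criterion when the recognition trials
  are evaluated as *ability* measures.
* **Decision rules.** TOMM Trial-1 and Word Choice Test rules (the latter
  fails on accuracy ≤ 47 *or* time-to-completion ≥ 156 s), single-threshold
  EVI rules, the combined two-trial rule (fail only if *both* recognition
  trials are at/below the cutoff), and strict below-chance detection
  (FCR < 12, the expectation of 24 two-alternative guesses).
* **Accuracy engine.** 2×2 cross-tabulation with Borderline exclusion,
  sens/spec/ACC (= mean of sens and spec), BR_Fail, cutoff sweeps,
  rank-based AUC (the Mann–Whitney probability that a criterion-positive
  case scores more extreme than a criterion-negative one, ties ½) with
  Hanley–McNeil or DeLong 95% CIs, and specificity-first cutoff selection.
* **Contrast statistics.** Pooled/Welch t-tests, Levene flagging, Cohen's
  *d* from summary statistics using the equal-weighted pooled SD
  `d = (m1 − m2) / sqrt((s1² + s2²)/2)`, the pooled two-proportion z-test,
  Pearson r with r², and cumulative-frequency tables.
* **Clinical banding.** The five-band interpretation scheme for recognition
  scores (Invalid 0–14, Questionable 15–17, Inferior 18–19, WNL 20–22,
  Superior 23–24) and banded distribution reports.
* **A cohort simulator.** Latent credibility status plus three correlated
  ability factors generate full score profiles; bundled presets are
  moment-matched to a disability-claim clinical sample (n = 52, ~40%
  non-credible) and an incentivized student sample (n = 83, ~9%), so every
  pipeline stage can run and be validated without patient data.

## Worked example

Calibrate the forced-choice trial as an EVI against the memory validity
composite on a simulated clinical cohort:

```python
from dataclasses import replace
import pvcalib as pv

cfg = replace(pv.preset("clinical_2021"), n=200)
cohort = pv.simulate_cohort(cfg, seed=42)

spec = pv.list_builtin_specs()["EI5_MEM"]
decisions = [pv.score_composite(r, spec) for r in cohort.records]
scores = cohort.scores("rcft_fcr")
rows = pv.cutoff_sweep(scores, decisions, [15, 16, 17, 18])
for r in rows:
    print(f"<= {r.cutoff}: BR_fail={r.br_fail:.3f}  sens={r.sens:.2f}  "
          f"spec={r.spec:.2f}  acc={r.acc:.2f}  (n={r.n_used}, "
          f"borderline excluded={r.n_excluded_borderline})")
rec = pv.select_cutoff(rows)
print(f"recommended cutoff: <={rec.cutoff:.0f} (spec={rec.spec:.2f}, "
      f"sens={rec.sens:.2f}, meets desired .90: {rec.meets_desired})")
res = pv.auc(scores, decisions)
print(f"AUC={res.auc:.2f}  95% CI=({res.ci95[0]:.2f}, {res.ci95[1]:.2f})  [{res.method}]")
```

prints

```
<= 15: BR_fail=0.120  sens=0.33  spec=0.96  acc=0.65  (n=138, borderline excluded=34)
<= 16: BR_fail=0.200  sens=0.58  spec=0.91  acc=0.75  (n=138, borderline excluded=34)
<= 17: BR_fail=0.285  sens=0.70  spec=0.84  acc=0.77  (n=138, borderline excluded=34)
<= 18: BR_fail=0.365  sens=0.76  spec=0.79  acc=0.77  (n=138, borderline excluded=34)
recommended cutoff: <=16 (spec=0.91, sens=0.58, meets desired .90: True)
AUC=0.84  95% CI=(0.75, 0.93)  [hanley_mcneil]
```

Reading the output: at the ≤ 16 cutoff, 20% of the cohort fails the
predictor; among composite-Fail examinees 58% are caught (sensitivity) while
91% of composite-Pass examinees are spared (specificity), which clears the
desirable .90 specificity standard — so the selector recommends ≤ 16, the
most liberal qualifying cutoff. The 34 Borderline composites (values 2–3)
are excluded from the 2×2 tables, a bookkeeping detail that silently changes
n and is therefore always reported.

The same analyses are available from the shell:

```sh
pvcalib simulate --preset clinical_2021 --n 200 --seed 42 --out cohort.csv
pvcalib score --cohort cohort.csv --composite EI5_MEM
pvcalib accuracy --cohort cohort.csv --predictor rcft_fcr \
    --criterion EI5_MEM --cutoffs 15,16,17,18
pvcalib report --preset clinical_2021 --preset student_2021 --seed 7 --out report/
```

`report` writes CSV analogues of the study-style tables (component base
rates, group contrasts, EVI accuracy sweeps, ability prediction, banded
distributions) plus a tidy contrast file and a run log.

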