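# vocfit

Non-invasive risk stratification for colorectal **polyp surveillance**.

Patients with previously detected colonic polyps undergo repeat colonoscopy at
guideline intervals, which consumes a large share of endoscopy capacity even
though most of these examinations find nothing that changes management. Two
cheap, non-invasive tests can triage that queue: the quantitative **faecal
immunochemical test** (FIT, µg Hb/g faeces) and a urinary
**volatile-organic-compound** (VOC) classifier score in [0, 1]. The clinical
outcome of interest is a *high-risk finding*: ≥2 premalignant polyps including
≥1 advanced polyp, or ≥5 premalignant polyps.

`vocfit` is a small biostatistics package, for epidemiologists and
screening-programme modellers, that implements the full evaluation pipeline
for this triage problem:

- **Threshold diagnostics** — confusion counts, sensitivity/specificity/PPV/NPV
  with Wilson or Clopper–Pearson intervals, threshold sweeps, ROC operating
  points and trapezoidal AUC.
- **Likelihood-ratio test combination** (the numerical content of Fagan's
  nomogram). A test with sensitivity *Se* and specificity *Sp* updates pre-test
  odds *O* = π/(1−π) to post-test odds *O*·LR, with
  LR⁺ = Se/(1−Sp) and LR⁻ = (1−Se)/Sp.
  *Serial* testing chains the negative branch (the second test is given only to
  first-test negatives); *parallel* testing treats the pair as one composite
  test that is negative only if both are.
- **Cohort-flow accounting** — per-1000-patient decision trees for each
  strategy: test positives, findings detected and missed, colonoscopies
  required, and the *number needed to scope* (NNS = colonoscopies per finding
  detected).
- **Synthetic cohorts** — class-conditional log-normal (FIT) and Beta (VOC)
  marker models quantile-calibrated to published operating points, drawn with a
  single reproducible seed, so the whole pipeline runs without patient data.
- **Cross-validation harness** — a seeded k-fold (default k = 3) out-of-fold
  scoring loop with ROC-based threshold selection (Youden's J or a target
  sensitivity), exposed both as functions and as a scikit-learn-compatible
  estimator (`ScoreThresholdClassifier`).

## Worked example

A surveillance population with a high-risk-finding prevalence of 26% takes the
VOC test (Se 0.94, Sp 0.69) first and, if negative, FIT at the 10 µg/g cutoff
(Se 0.54, Sp 0.79):

```python
from vocfit import TestSpec, as_percent, flow_serial, serial_chain

voc = TestSpec("VOC", 0.94, 0.69)
fit = TestSpec("FIT", 0.54, 0.79)

chain = serial_chain(0.26, [voc, fit])
print([as_percent(u.post_test_prob_negative) for u in chain.updates])
print(as_percent(chain.total_probability_reduction))

flow = flow_serial(1000, 0.26, voc, fit)
print(flow.summary.colonoscopies, flow.summary.detected_in_positives,
      flow.summary.number_needed_to_scope)
```

prints

```
[3, 2]
24
590 253 2
```

i.e. a patient negative on VOC has a 3% residual probability of a high-risk
finding, 2% after a second negative on FIT — a 24-point reduction from the
26% prior. Per 1000 patients, the serial strategy needs 590 colonoscopies
(474 VOC-positives + 116 FIT-positives among VOC-negatives), detects 253 of
the 260 findings, and scopes 2 patients per finding detected — versus 1000
colonoscopies and NNS 4 when everyone is scoped.

The same workflow is available from the shell:

```bash
vocfit simulate --n 255 --seed 0 --out cohort.csv
vocfit evaluate --cohort cohort.csv --marker fit
vocfit fagan --pre 0.26 --test VOC:0.94:0.69 --test FIT:0.54:0.79 --mode serial
vocfit flow --strategy serial --test VOC:0.94:0.69 --test FIT:0.54:0.79
vocfit cv --cohort cohort.csv --k 3 --seed 0
vocfit reproduce --out repro --check
```

`vocfit reproduce --check` rebuilds the full accuracy table, ROC, Fagan chain
and cohort-flow table and exits non-zero if any headline cell deviates.

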