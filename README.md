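# breathdx

Analysis pipeline for electronic-nose (e-nose) breath tests of the kind
used to screen for lung cancer: a 32-channel conducting-polymer
chemiresistive array measures a bagged alveolar-air sample, and the pattern
of fractional resistance changes across channels is classified as case or
control. The package is aimed at researchers developing or auditing such
breath tests who need every stage — signal processing, scaling,
repeatability, validation, accuracy arithmetic — reproducible and testable
without access to raw instrument data.

It provides:

- a **synthetic cohort generator** with known ground truth: three-phase
  resistance sweeps (10 s baseline purge, 40 s sample purge, 10 s washout),
  10 replicate measurements per subject with a contaminated first replicate
  and occasional baseline drift;
- **feature extraction**: per channel, ΔR/R0 = (Rmax − R0)/R0, with
  automated replicate quality control (delete measurement 1, delete
  drifted measurements, average the rest);
- **chemometric scaling**: per-sample vector normalization
  (∑ₖ x²ᵢₖ = 1) then per-sensor autoscaling x′ᵢₖ = (xᵢₖ − x̄ₖ)/sₖ, fitted on
  training data only;
- **sensor repeatability**: ICC(3,k) — two-way fixed, consistency,
  average-measures — of each measurement against the 2nd, and within-subject
  coefficients of variation;
- **repeated double cross-validation**: inner 80/20 calibration split
  (training / internal validation), outer untouched external-validation
  cohort; LDA (with shrinkage when n < 2p) and RBF SVM tuned by inner CV;
- **diagnostic accuracy**: sensitivity, specificity, PPV, NPV, FP/FN
  rates, accuracy, Mann–Whitney AUC with DeLong 95% CI; the sample-size
  rule n = ⌈C(100 − C)/SE²⌉; and forensic **reconstruction of integer
  confusion matrices from rounded published percentages**, including proofs
  of inconsistency when no matrix fits.

## Worked example

Recover the confusion matrix behind a published external-validation row
(12 cases, 29 controls, sensitivity 75.0%, specificity 96.6%):

```python
>>> from breathdx import reconstruct_confusion, compute_metrics
>>> res = reconstruct_confusion({"sensitivity": 75.0, "specificity": 96.6},
...                             n_cases=12, n_controls=29)
>>> cm = res.solutions[0]
>>> (cm.tp, cm.fn, cm.fp, cm.tn)
(9, 3, 1, 28)
>>> compute_metrics(cm).rounded()
{'sensitivity': 75.0, 'specificity': 96.6, 'ppv': 90.0, 'npv': 90.3,
 'fp_rate': 3.4, 'fn_rate': 25.0, 'accuracy': 90.2}
```

The search is exhaustive, so a unique solution means those counts are the
*only* integers consistent with the printed row — and the implied accuracy
is 37/41 = 90.2%, which is how a typo in a published accuracy cell can be
proven rather than suspected.

End to end on synthetic data (`python examples/03_double_cross_validation.py`):

```
internal: sens 81.8% spec 94.7% acc 90.0% AUC 0.97 (95% CI 0.92-1.00)
external: sens 66.7% spec 82.8% acc 78.0% AUC 0.82 (95% CI 0.67-0.98)
```

The internal row evaluates the 20% hold-out of the calibration cohort; the
external row is the honest estimate on a cohort never touched during
scaling, training or model selection — it is typically lower, and that gap
is the point of the nested design.

The `examples/` directory has one short script per capability (simulation
and extraction, repeatability, nested validation, table reconstruction,
sample size). A thin CLI wraps the same functions:

```bash
breathdx simulate --config sim.yaml --out cohort.csv --truth truth.json --seed 7
breathdx extract --in cohort.csv --out features.csv --drift-tol 0.01
breathdx reliability --in cohort.csv
breathdx validate --features features.csv --external external.csv --learner svm
breathdx reconstruct --sens 75.0 --spec 96.6 --cases 12 --controls 29
breathdx samplesize --accuracy 80 --se 3
breathdx run --out rundir --seed 1
```

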