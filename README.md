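# traumapanel

Severe traumatic injury triggers an immediate, massive release of immune
mediators — interleukins, chemokines, interferons, TNF-superfamily ligands —
and their soluble receptors into the circulation.  How this "cytokine storm"
evolves over the first 72 hours, and how its trajectory differs between
patients who recover quickly and those who die or remain critically ill,
can be read out from longitudinal plasma proteomics on an aptamer-based
panel.  `traumapanel` is an analysis pipeline for exactly this design:

* **Cohort structure** — trauma patients split by outcome into early
  non-survivors (ENS: death ≤ 72 h, sampled at 0 h only), resolvers
  (R: alive at 30 d, < 7 ICU days) and non-resolvers (NR: death after 72 h
  or ≥ 7 ICU days), plus minimally injured controls (ISS ≤ 1); plasma drawn
  at 0, 24 and 72 h.
* **Panel preprocessing** — sample-level QC on hybridization (0.4–2.5) and
  calibration (0.8–1.2) scale factors; extraction of a 184-analyte immune
  panel (115 mediators, 69 soluble receptors); removal of analytes with
  > 20 % missing values; minimum-value imputation (detection-limit proxy);
  log2 transformation.
* **Differential statistics** — per-(group, timepoint) z-score heatmap
  matrices; normality-gated two-group tests (Shapiro–Wilk → Welch t or
  Mann–Whitney U); ANOVA/Tukey or Kruskal–Wallis/Dunn for multi-group
  contrasts; Benjamini–Hochberg correction; NR-vs-R volcano tables flagging
  analytes with ≥ 1.5-fold change and adjusted p < 0.05.
* **Case-control matching** — greedy caliper matching of NR to R patients on
  age, sex and ISS, with a post-match balance report.
* **Outcome prediction** — the core resampling engine: in each of B
  iterations, draw a bootstrap sample of 112 patients with replacement,
  standardize on the in-bag statistics, select features by L1-penalized
  (LASSO) logistic regression, train a linear-kernel SVM on the selected
  features, and score the out-of-bag patients.  The B out-of-bag AUROC
  values give a median and 2.5/97.5-percentile interval; a label-permuted
  control ensemble sharing the same bootstrap draws provides the null, and
  a one-sided paired signed-rank test the significance.  Feature importance
  is the quadratic mean of each feature's SVM weights over all iterations,
  rescaled so the maximum is 100.  PLS-DA provides the class-separation
  projection, and a secondary model adds ISS, age and sex as features.

Because patient-level trial data are not public, the package ships a
calibrated synthetic cohort generator (`traumapanel.synthetic`) that
reproduces the measurement structure above — group sizes 38/34/78 + 29,
Table-style covariate distributions, an early mediator release scaled by
outcome group and injury severity, a planted "delayed" mediator subset that
rises at 24–72 h more strongly in non-resolvers, log-normal noise, and
detection-limit-driven missingness — together with a ground-truth ledger so
every stage of the pipeline can be validated by recovery tests.

## Worked example

The numbered scripts under `analysis/` run the full workflow on a simulated
cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py           # cohort + expression matrix
python analysis/02_qc_preprocess.py             # QC gate + panel preprocessing
python analysis/03_differential_analysis.py     # heatmaps, volcanoes, summary
python analysis/04_match_cohort.py              # NR-to-R caliper matching
python analysis/05_predict_outcomes.py          # bootstrap LASSO->SVM engine
```

With the default seed (42) this prints, among other things:

```
QC gate: 7596 records, 7211 in range (94.9% pass)
panel: 184 analytes ({'IL': 40, 'IL_R': 38, 'IFN': 27, 'TNFRSF': 26, 'CCL': 23, 'TNFSF': 15, 'CXCL': 10, 'IFN_R': 5})
72h: 17 mediators with >=1.5-fold NR/R difference at adjusted p<0.05; top: IFN015, TNFSF011, IL002, CXCL003, IL019
matched 35 NR cases to 29 R controls
post-match balance: age diff -2.61 y (p=0.465), ISS diff 3.47 (p=0.111), sex p=0.717
[mediators] median OOB AUROC 1.000 [0.990, 1.000] vs permuted control 0.500; p = 4.42e-35
[mediators] top predictors: IFN015=100, CCL020=75, TNFSF006=71, TNFSF011=71, IL002=69
```

Reading this: the scale-factor gate reproduces the assay-level pass rate;
the immune panel splits into its eight families; at 72 h the volcano flags
exactly the planted delayed-subset mediators; matching yields
balanced-but-unequal groups (35 vs 29, all balance p > 0.1); and the
prediction ensemble separates resolvers from non-resolvers far better than
its label-permuted control (which sits at the chance AUROC of 0.5).  The
synthetic delayed effect (a 1.0 log2-unit NR shift at 72 h) is deliberately
clean, so the ensemble reaches higher AUROC than noisy clinical data would.

There is also a `traumapanel` console script exposing the same stages
(`simulate`, `qc`, `analyze`, `match`, `predict`, `run`); `run` executes the
whole pipeline from a YAML config and writes a machine-readable run report.

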