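# lesiondyn

Lesion-level tumor heterogeneity analysis for clinical trial data.

In solid-tumor trials, tumor burden is usually collapsed into a single sum
over all target lesions (the RECIST SLD in mm, or the bidimensional SOPD in
mm²).  That sum hides a clinically meaningful signal: within one patient,
individual target lesions (iTLs) in different organs can respond very
differently to the same drug — the liver metastases may shrink while a lung
lesion keeps growing.  `lesiondyn` quantifies this heterogeneity from
routine tumor-size follow-up and links it to overall survival (OS).  It is
aimed at pharmacometricians and biostatisticians deciding whether a
tumor-size model (or a survival analysis) needs lesion-level structure.

## Method

Given long-format lesion measurements (patient × lesion × visit) and a
patient covariate table, the pipeline runs four stages:

1. **Classification.**  Each lesion is assigned to an organ class (Liver,
   Lung, Lymph node, …) by keyword rules on its free-text location; primary
   (non-metastatic) lesions and lesions without location text get reserved
   classes, and classes with fewer than 30 patients are pooled into
   "Other".  Per patient and class, lesion sizes are summed into a
   class-related target lesion (cTL).

2. **Cross-correlation.**  The similarity of two size time courses
   x, y on their shared visits is the cross-correlation coefficient

       CC(ℓ) = corr(x[i], y[i+ℓ]),   CC ∈ [−1, 1],

   a Pearson correlation over the lag-overlapped window, evaluated at zero
   shift and maximized over integer visit shifts ℓ up to ±12.  CC ≈ 1 means
   similar dynamics, CC ≈ −1 opposite dynamics.  The *inter-class* analysis
   correlates cTL pairs within a patient (liver–lung, liver–node, …); the
   *intra-class* analysis correlates lesion pairs within one organ.

3. **Clustering.**  The CC values are grouped by exact 1-D K-means
   (dynamic programming over contiguous partitions), with k fixed at 3 by
   convention or selected by the elbow of the SSE(k) curve.  Clusters are
   numbered by ascending centroid: centroids below −0.35 indicate
   *different* dynamics, above +0.35 *similar* dynamics, in between
   *undefined*.

4. **Survival linkage.**  Each patient's heterogeneity metric is the
   median of their zero-shift inter-class CCs.  It enters Kaplan–Meier /
   log-rank comparisons (dichotomized at 0.35) and a multivariate Cox model
   alongside ECOG status, baseline tumor size TS0, early tumor shrinkage
   ETS = (TS0 − TS8)/TS0 at week 8, and KRAS status, optionally with a
   KRAS × CC interaction.

Because real multi-lesion oncology datasets are proprietary, the package
ships a first-class synthetic trial generator (`lesiondyn.simulate`) with
biexponential shrink/re-growth lesion trajectories
`TS(t) = B·(e^(−k_s t) + e^(k_g t) − 1)`, divergent / stable / responding
organ classes, visit-delayed responses, covariates and CC-dependent
censored survival, plus a truth log for parameter-recovery testing.

## Worked example

```bash
python examples/05_survival_link.py
```

prints, for a 600-patient simulated trial:

```
cetuximab-arm patients:        301
with median CC (>=2 classes):  147
median OS, high CC group:       60.3 weeks (95% CI 32.4-87.9; 64 patients, 50 deaths)
median OS, low  CC group:       29.5 weeks (95% CI 20.3-35.7; 83 patients, 78 deaths)
log-rank:                      chi2 = 13.15 (df 1), p = 0.0003
Cox HR per unit median CC:     0.706 (95% CI 0.545-0.916, p = 0.0087)
```

Patients whose lesions evolve concordantly (median CC > 0.35) live about
twice as long in this simulation, and the Cox model attributes a ~30% drop
in death hazard to each unit increase of the median CC — heterogeneous
lesion dynamics carry prognostic information beyond total tumor size.
The other examples (`examples/01…04`) walk through simulation,
classification, cross-correlation and clustering individually.

## Layout

- `src/lesiondyn/trial_data.py` — table I/O, validation, preprocessing,
  series assembly, total tumor size
- `src/lesiondyn/classify.py` — keyword ruleset, organ classification,
  rare-class merging, class summaries
- `src/lesiondyn/crosscorr.py` — lagged cross-correlation of series pairs
- `src/lesiondyn/heterogeneity.py` — cTLs, pair enumeration, exact 1-D
  K-means, elbow selection, cluster reports
- `src/lesiondyn/survival.py` — median CC, dichotomization, ETS,
  Kaplan–Meier / log-rank / Cox (via lifelines)
- `src/lesiondyn/simulate.py` — synthetic trial generator and fixtures
- `src/lesiondyn/pipeline.py` — end-to-end driver and CSV/JSON outputs

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
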