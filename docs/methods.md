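# Methods

## Data model and preprocessing

The unit of observation is one size measurement of one target lesion at one
assessment visit.  Time is continuous, in weeks since baseline (the first
tumor assessment), not a visit index.  Sizes are non-negative: mm for the
longest-diameter metric (SLD) or mm² for the product-of-diameters metric
(SOPD).  The two metrics are never mixed within a run; an input table with
mixed metrics is rejected.

Two exclusion rules precede every analysis: (a) patients whose assessments
all fall on one visit are removed (a single point has no dynamics); (b) for
patients with a recorded tumor-surgery time, measurements strictly after
surgery are removed — surgery changes lesion sizes by means unrelated to
drug effect.  The truncation is record-level, not patient-level: the
pre-surgery series remains informative, and dropping whole patients would
discard valid follow-up.  Rule (a) is re-applied after (b).  Preprocessing
is idempotent and reports per-rule exclusion counts.

Total tumor size at a landmark (TS0, TS8) sums the lesions measured at the
assessment visit nearest the landmark within a tolerance (default 2 weeks;
protocols window their visits, and no visit-matching rule is dictated by
the data themselves).  Ties prefer the earlier visit.  A patient with no
qualifying visit has a missing landmark value — missingness is a value,
never an error, and propagates into the early-shrinkage ratio
ETS = (TS0 − TS8)/TS0.

## Organ classification

Classification is deliberately mechanical: case-insensitive substring
matching of keywords on the normalized (uppercased, punctuation-stripped)
location text, first match wins in ruleset order.  No stemming, no
ontology — the dialect is trivial to reproduce and the ruleset file is the
single point of expert control.  Primary (non-metastatic) lesions are
classified by lesion *type*, overriding location; missing or unmatched text
yields "Unclassified lesions".  The shipped default ruleset is a
reconstruction of a plausible mCRC keyword set (liver / lung / lymph node /
other respiratory / other digestive / other specified) and should be
reviewed against the wording of any real dataset.

Classes other than Liver, Lung and Lymph node are pooled into "Other" when
they hold fewer than 30 distinct patients (strictly fewer: a class with
exactly 30 is kept).  The three main metastatic sites are exempt because
they are the classes of scientific interest and are always reported
separately.  Merging relabels; it never changes lesion counts.

## Cross-correlation

The similarity of two aligned size vectors is the Pearson product-moment
correlation computed on the lag-overlapped window, mean-centered and
normalized by the overlap's own standard deviations.  Overlap-only
normalization is what guarantees CC ∈ [−1, 1] at every lag; whole-series
normalization does not.  Lags are integer shifts in assessment index
(visits are protocol-synchronized within a patient), searched over
ℓ = −L..L with L = min(12, n−2), so a pair with n shared visits always
keeps at least two overlapping points.

Numerical conventions:

- With exactly two points the correlation is the sign of the joint step,
  returned exactly as ±1 (or undefined when either step is zero).
- A window whose spread is zero up to float round-off relative to its
  magnitude (relative tolerance 1e−9) is flat: its correlation is
  undefined (NaN).  Undefined CCs are excluded from clustering and from
  median-CC derivation and are counted in diagnostics.
- `best_lag` maximizes the lag profile; ties (within 1e−12) break toward
  the smallest |lag|, then toward the negative lag.  Pairs with only two
  shared visits therefore always report lag 0.
- Alignment requires exact time equality by default; a positive tolerance
  greedily pairs nearest visits for datasets with jittered visit dates.

Class-level series (cTLs) sum a patient's lesions of one class over
complete-case visits only — a visit enters the sum iff every lesion of the
class was measured there — so partially missing visits can never fake a
size drop.  Classes retaining fewer than two visits are dropped from the
inter-class analysis.

## Clustering and elbow selection

CC values are clustered in one dimension.  Because optimal 1-D minimum-SSE
clusters are contiguous intervals of the sorted values, the assignment is
computed *exactly* by dynamic programming over split points (O(k n²),
the Ckmeans.1d.dp approach) instead of randomized Lloyd iterations: the
result is globally optimal, deterministic, and independent of seeds or
restart counts (both are still accepted in the API for interface
stability).  Clusters are renumbered 1..k by ascending centroid, so
"cluster 1" is always the most negative one.  Interpretation cutoffs
follow the ±0.35 convention: centroid < −0.35 → different dynamics,
> +0.35 → similar, else undefined.  Reported per cluster: centroid, % of
CC pairs (sums to 100), % of patients (a patient counts in every cluster
where it has a pair, so the column may sum above 100), and the histogram
of best lags.

The default cluster count is k = 3 (different / undefined / similar); the
elbow diagnostic is available as `choose_k_elbow`.  The elbow is the k of
maximum curvature of **log** SSE(k): the raw second difference is
dominated by the large absolute drop from k=1 to k=2 and would report an
elbow at 2 for any well-separated structure, whereas the relative
(log-scale) drop collapses exactly after the true group count.  With
fewer than k_max+1 distinct values, k_max shrinks with a warning.

## Survival linkage

The per-patient heterogeneity metric is the median of the defined
zero-shift inter-class CCs (even counts take the midpoint of the central
pair).  Patients with lesions in a single class have no pair and are
excluded from CC-based survival analyses rather than imputed.  The metric
is dichotomized at 0.35 ("low" = median CC ≤ 0.35, heterogeneous), with
0.5 available as a sensitivity setting, and analyses default to the
cetuximab arm (configurable).

Survival machinery comes from lifelines and is treated as a black box
validated against hand computations in the test suite: Kaplan–Meier
product-limit curves with Greenwood/log-log confidence bands (the median's
CI inverts the band), the multi-group log-rank test, and Cox proportional
hazards with Efron tie handling and Wald intervals.  The model
specification mirrors the standard multivariate set: ECOG (binary), TS0
(continuous), ETS at week 8 (continuous), KRAS (binary) and the median CC
(continuous or binary), optionally plus a KRAS × median-CC interaction.
Rows missing any included term are dropped per fit.

## Synthetic trial generator

The generator emulates the structure of an mCRC cetuximab trial so that
every pipeline stage can be exercised and checked against ground truth
without clinical data.

- **Schedule:** baseline plus every 8 weeks to week 48 (the week-8 ETS
  landmark granularity); each post-baseline assessment is missed with
  probability 0.05.
- **Organ involvement:** 1–3 organ classes per patient with
  P = (0.62, 0.28, 0.10) — so ~38% of patients qualify for the
  inter-class analysis, the eligibility scale seen in large mCRC trials —
  drawn liver-dominant (liver 0.52, lung 0.16, lymph node 0.17, other
  0.15, the "other" split between digestive and specified sites), plus a
  primary-site lesion with probability 0.15.  Lesion counts are
  1 + Poisson(0.8) per organ, capped at 5 per organ and 10 per patient.
- **Trajectories:** `TS(t) = B·(e^(−k_s t) + e^(k_g t) − 1)` — a
  closed-form shrink/re-grow curve standard in tumor-size modeling.  Each
  class is *responding* (k_s = 0.04/wk, k_g = 0.005/wk; shrink half-life
  ≈ 17 wk), *divergent* (progressing: k_s = 0.005, k_g = 0.025,
  probability `p_div`, default 0.25 — the expected opposite-dynamics pair
  share 2·p(1−p−p_stable) then sits near the ~36% seen in cetuximab-arm
  analyses) or *stable* (flat latent curve, probability 0.10, chosen so
  noise-dominated near-zero CC pairs make up roughly the ~18% middle
  cluster observed in practice).  With probability 0.10 a class responds
  one visit late.  Baseline sizes are lognormal (median 30 mm, σ = 0.5,
  floor 10 mm); per-patient lognormal rate multipliers (σ = 0.2) create
  between-patient variability; KRAS-mutated patients (prevalence 0.40)
  have their shrink rate halved.  Observations add lesion-level lognormal
  measurement noise (σ = 0.08, an 8% CV on the RECIST inter-reader scale)
  and are rounded to whole mm (SLD) or squared rounded diameters (SOPD).
- **Survival:** exponential baseline hazard 0.008/wk multiplied by
  exp(Σβx) with centered covariates: β = log 0.74 per unit of the TRUE
  noise-free between-class concordance (median zero-shift CC of the
  latent class curves; a pair involving a flat class contributes 0 — "no
  relation"; single-class patients sit at 1), log 0.5 per unit true ETS,
  log 1.6 for ECOG-impaired, 0.003 per mm baseline size.  Censoring is an
  independent exponential (0.002/wk) plus administrative cut-off at week
  160.
- **Reproducibility:** one global seed spawns per-patient substreams
  (`SeedSequence(seed, spawn_key=(i,))`), so patient i's data are
  invariant to `n_patients`.
- **Truth log:** per patient, the classes, dynamic types, delays, true
  pairwise and median concordance, true TS0/ETS and the linear predictor;
  `divergent_pair_fraction` summarizes the realized share of
  response-vs-progression pairs, the ground truth the cluster-1 share
  estimates.

What the generator does **not** emulate: new-lesion appearance and
non-target lesions, pharmacokinetics, informative censoring or visit
schedules tied to progression, correlated measurement error between
lesions read on the same scan, and organ-specific response biology beyond
the three dynamic types.  Passing recovery tests therefore show the
pipeline is a consistent estimator of its own generative model at trial
scale, not that the clinical effect sizes are reproduced.

## Problem sizes used by the checks

The simulation-based checks run at 500 patients (heterogeneity-fraction
recovery, one trial per setting), 100 replicates of 1,000 patients (Cox
coverage of the true hazard ratio), and 1,000 replicates of 300 patients
(log-rank type-I error under the all-β-zero null; ~35 patients in the
smaller CC group keeps the χ² approximation honest).  The acceptance
script reports a single 500-patient run.

## Known limitations

- Lags are visit-index shifts; irregular real-world visit timing beyond
  the alignment tolerance is not modeled (no interpolation by design).
- The median-CC metric conditions on having ≥ 2 tumor assessments and
  ≥ 2 organ classes; as the number of assessments depends on survival
  itself, immortal-time bias cannot be excluded, and time-dependent
  covariate models are out of scope.
- The default ruleset is a reconstruction; results on real data depend on
  auditing it against the dataset's location vocabulary.
- Whether zero-shift and maximized CCs should be clustered jointly or
  separately is not uniquely defined; both modes are provided
  (`use_max_cc`), each clustering its own values.
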