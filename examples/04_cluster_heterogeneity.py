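"""Inter-class heterogeneity analysis with K-means clustering.

Simulates a trial, builds per-organ summed series (cTLs), computes the
zero-shift CC of every within-patient class pair, clusters the CCs with
exact 1-D K-means (k = 3 by convention; the elbow diagnostic is printed),
and reports the per-cluster summary table.
"""

import numpy as np

from lesiondyn import (SimConfig, build_series, choose_k_elbow, classify_all,
                       divergent_pair_fraction, merge_rare_classes, preprocess,
                       simulate_trial)
from lesiondyn.heterogeneity import (build_all_ctls, cluster_cc,
                                     cluster_report, interclass_pairs)

records, covariates, truth = simulate_trial(SimConfig(n_patients=400, seed=12))
kept, _ = preprocess(records, covariates)
series = build_series(kept)
classified, _ = merge_rare_classes(classify_all(series))
inter = interclass_pairs(build_all_ctls(series, classified))

values = np.array([r.cc_zero for r in inter if np.isfinite(r.cc_zero)])
print(f"inter-class CC pairs: {values.size} "
      f"(from {len({r.patient_id for r in inter})} multi-organ patients)")
print(f"elbow-selected k:     {choose_k_elbow(values, k_max=6)}")

result, kept_records = cluster_cc(inter, k=3)
report, lag_hist = cluster_report(result, kept_records)
print("\nzero-shift cluster table (cluster 1 = lowest centroid):")
print(report.round(3).to_string(index=False))

share1 = report.loc[report.cluster == 1, "pct_pairs"].iloc[0]
print(f"\ncluster-1 pair share:      {share1:.1f}%")
print(f"true divergent pair share: {100 * divergent_pair_fraction(truth):.1f}%")
print("Cluster 1 (centroid < -0.35) collects the lesion pairs with opposite")
print("dynamics; its share estimates the true divergent-pair fraction.")
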