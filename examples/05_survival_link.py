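"""Linking the median-CC heterogeneity metric to overall survival.

Runs the full pipeline on a simulated trial and prints the Kaplan-Meier
medians by CC group, the log-rank test, and the multivariate Cox model
with the median CC entered continuously.
"""

from lesiondyn import PipelineConfig, SimConfig, run_pipeline, simulate_trial

records, covariates, _ = simulate_trial(SimConfig(n_patients=600, seed=42))
result = run_pipeline(records, covariates,
                      PipelineConfig(seed=0, run_intra=False))

out = result.outcomes
print(f"cetuximab-arm patients:        {len(out)}")
print(f"with median CC (>=2 classes):  {out['median_cc'].notna().sum()}")

for label in ("high", "low"):
    km = result.km[label]
    lo, hi = km.median_ci
    print(f"median OS, {label:4s} CC group:     {km.median:6.1f} weeks "
          f"(95% CI {lo:.1f}-{hi:.1f}; {km.n} patients, {km.n_events} deaths)")

stat, dof, p = result.logrank
print(f"log-rank:                      chi2 = {stat:.2f} (df {dof}), p = {p:.4f}")

fit = result.cox_continuous
row = fit[fit["term"] == "median_cc"].iloc[0]
print(f"Cox HR per unit median CC:     {row['hr']:.3f} "
      f"(95% CI {row['hr_ci_low']:.3f}-{row['hr_ci_high']:.3f}, p = {row['p']:.4f})")
print()
print("An HR below 1 means that patients whose lesions evolve concordantly")
print("(median CC near 1) have a lower death hazard than patients with")
print("discordant lesion dynamics - tumor heterogeneity carries risk.")
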