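"""Rule-based organ classification of free-text lesion locations.

Classifies a handful of case-report-form style location strings, then
shows the class summary table ("cTL (iTL)" = patients with the class
(individual lesions)) for a small synthetic trial, after pooling rare
classes into "Other".
"""

from lesiondyn import (ClassRuleset, SimConfig, build_series, classify_all,
                       classify_lesion, class_summary, format_class_summary,
                       merge_rare_classes, preprocess, simulate_trial)

ruleset = ClassRuleset.default()

for text, ltype in [("LIVER right lobe", "metastatic"),
                    ("mesenteric lymph nodes", "node"),
                    ("Pulmonary nodule RLL", "metastatic"),
                    ("sigmoid colon", "primary"),
                    ("", "metastatic")]:
    c = classify_lesion("P1", "L1", text, ltype, ruleset)
    print(f"{text or '<missing>':28s} ({ltype:10s}) -> {c.class_name}")

records, covariates, _ = simulate_trial(SimConfig(n_patients=150, seed=2))
kept, _ = preprocess(records, covariates)
series = build_series(kept)
classified, merge_report = merge_rare_classes(classify_all(series, ruleset))

print(f"\nclasses pooled into 'Other': {sorted(merge_report.merged_classes)}")
cet = {c.patient_id for c in covariates if c.arm == "cetuximab"}
table = class_summary(classified, {"ALL": list(classified), "cetuximab": cet})
print("\nclass summary, 'patients (lesions)':")
print(format_class_summary(table).to_string())
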