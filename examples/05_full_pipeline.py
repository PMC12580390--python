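"""Full pipeline on a synthetic cohort.

Simulates the small imaged subgroup (11 chemoimmunotherapy-treated
squamous patients, 7 responders vs 4 non-responders) with weaker CAF–TAEC
coupling in responders, then runs the whole cascade: phenotype gating →
per-patient metrics → group comparisons → median-split odds ratios → ROC.
The report bundle is written as CSV + a JSON manifest.
"""

from spatialtme import RunConfig, run_pipeline

report = run_pipeline(RunConfig(simulate_preset="naic-scc-mif", seed=11,
                                out_dir="scratch/example_bundle"))

print("group comparison (responders vs non-responders):")
cols = ["metric", "MPR_summary", "NMPR_summary", "p_printed"]
print(report.tme_comparisons[cols].to_string(index=False))
print()
print("ROC of the spatial metrics for predicting response:")
print(report.roc_summary[["metric", "auc", "sensitivity",
                          "specificity"]].to_string(index=False))
print()
print(f"bundle written to {report.out_dir}; "
      f"{report.manifest['n_statistical_tests']} tests run")
# Responders show larger nearest-neighbor distances and lower proximity
# counts; both metrics discriminate response with high AUC.
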