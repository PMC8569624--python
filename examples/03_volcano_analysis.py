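"""Stress-response volcano analysis on BLUE tables.

Fold change (WL/WW), Mann–Whitney tests with Benjamini–Hochberg FDR, and
the decrease / increase classification at the FC < 0.5 / > 2 thresholds.
"""

import pandas as pd

import leafmet as lm

sim = lm.SimConfig(seed=1)
design, truth = lm.generate_trial(sim)
mets = lm.generate_metabolome(design, truth, sim)
blues = lm.preprocess_table(design, mets)["blues"]
blues = lm.impute_knn(blues, k=10) if blues.isna().any().any() else blues

treatment = pd.Series([s.rsplit("_", 1)[1] for s in blues.index],
                      index=blues.index)
volcano = lm.volcano_table(blues, treatment)
summary = lm.volcano_classify(volcano, lm.generate_annotation(sim))

print(volcano[volcano.category != "none"].round(4).to_string())
print(f"\n{summary['pct_decrease']:.1f}% decrease, "
      f"{summary['pct_increase']:.1f}% increase "
      f"(planted: {sim.frac_responsive:.0%} responders at 4-fold)")
print(f"mean FC of increases: {summary['mean_fc_increase']:.2f} "
      f"+- {summary['sd_fc_increase']:.2f}  (planted value 4)")
print("\nclass tally of regulated metabolites:")
print(summary["class_summary"].to_string(index=False))
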