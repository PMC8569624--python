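"""Simulate one synthetic cotton field trial and look at its structure.

Builds the 22-genotype × 2-irrigation × 2-rep design (88 plots), draws
per-plot metabolite intensities with a planted stress response, and
generates five leaf reflectance spectra per plot.
"""

import leafmet as lm

sim = lm.SimConfig(seed=1)
design, truth = lm.generate_trial(sim)
metabolites = lm.generate_metabolome(design, truth, sim)
leaves = lm.generate_spectra(design, truth, sim)

print(f"plots: {len(design)}  (genotypes={design.genotype.nunique()}, "
      f"treatments={design.treatment.nunique()}, reps={design.rep.nunique()})")
print(design.head(4).to_string())
print(f"\nmetabolite table: {metabolites.shape[0]} plots x "
      f"{metabolites.shape[1]} metabolites, "
      f"{metabolites.isna().to_numpy().mean():.1%} missing")

resp = truth.responsive.sum()
print(f"planted stress responders: {resp} metabolites with |log2 FC| = "
      f"{sim.responsive_log2fc:g} (fold change {2**sim.responsive_log2fc:g} or "
      f"{2**-sim.responsive_log2fc:g})")

plots = lm.average_replicate_spectra(leaves, lm.leaf_to_plot(leaves))
print(f"\nleaf spectra: {leaves.n_samples} -> averaged to {plots.n_samples} "
      f"plot spectra on the {len(lm.WAVELENGTH_GRID)}-band 350-2500 nm grid")
r670 = plots.band(670).groupby(design["treatment"]).mean()
print("mean reflectance at 670 nm (chlorophyll absorption):")
print(r670.round(4).to_string())
print("WL leaves reflect more red light: stressed plants hold less chlorophyll.")
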