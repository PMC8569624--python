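"""PLSR estimation and prediction of a metabolite from 2151-band spectra.

Uses the calibrated coupled generator: 44 samples whose spectra carry
absorption features at 520/1450/1930 nm with depths linear in a latent
metabolite value, plus band noise set for a target predictive R² of 0.8.
"""

import pandas as pd

import leafmet as lm

ds = lm.generate_coupled_dataset(n_samples=44, true_r2=0.8, seed=7)
X = ds.spectra.to_array()
y = ds.y.to_numpy()

model = lm.full_dataset_model(X, y)
print(f"full dataset model: A = {model.A} latent variables, "
      f"training R^2 = {model.r2:.3f}")
print("RMSECV over A = 0..12:",
      [round(float(r), 3) for r in model.rmsecv])

cv = lm.fourfold_cv(X, y, seed=7)
print(f"\n4-fold CV: per-fold A = {cv.fold_A}, "
      f"per-fold Q^2 = {[round(q, 3) for q in cv.fold_q2]}")
print(f"mean Q^2 = {cv.q2_mean:.3f}, predicted = {cv.predicted} "
      f"(noise was calibrated for predictive R^2 ~= {ds.true_r2})")

betas = pd.DataFrame([model.beta], index=["met"], columns=lm.WAVELENGTH_GRID)
imp = lm.importance_analysis(betas)
top = (imp.histogram.query("group == 'overall'")
       .nlargest(5, "count")[["bin_left_nm", "bin_right_nm", "count"]])
print("\nmost-selected 50-nm bins (top-10% |beta| wavelengths):")
print(top.to_string(index=False))
print(f"planted band centers: {ds.coupled_centers} — the importance "
      f"analysis should recover them as selection-frequency peaks.")
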