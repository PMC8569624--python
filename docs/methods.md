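# Methods

`leafmet` implements a complete analysis chain for irrigation-stress
field trials in which every plot is phenotyped twice: chemically, as a
table of leaf metabolite intensities, and optically, as leaf reflectance
spectra on the 350–2500 nm, 1-nm grid (2151 bands). The chain has four
statistical layers — trial-level mixed models, stress-response
statistics, vegetation indices, and spectral regression — plus a
synthetic-trial generator that provides ground truth for all of them.

## Trial model and BLUEs

The trial is a randomized incomplete block design: 22 genotypes × 2
irrigation treatments (well-watered WW, water-limited WL) × 2 replicates
per treatment, 88 plots. For each trait y the full mixed model is

    y = μ + genotype + irg + genotype×irg
        + rep(irg) + block(rep×irg) + column(rep×irg) + ε,

with the first four terms fixed and the rest random. The fixed part is
parameterized directly by genotype×treatment cell means, so each BLUE
(best linear unbiased estimator of a cell mean, adjusted for the design
effects) is an element of the GLS coefficient vector. Variance
components are estimated by REML: the restricted likelihood is profiled
over the residual variance and maximized over the variance *ratios*
γ_i = σ²_i/σ²_ε with L-BFGS-B under γ_i ≥ 0, from three starting points.
Because the parameterization is cell-mean based, fixed-effect
singularity cannot arise; a cell emptied by missingness or outlier
removal simply becomes non-estimable and its BLUE is returned missing
with a warning. A fully saturated fit (one observation per cell) is
allowed but its residual variance is reported as zero with a warning.

Per-trait preprocessing runs in this order: (1) metabolite intensities
are divided by their within-year median (fiber traits and vegetation
indices skip this step and enter on their raw scale); (2) a Box–Cox
power transform is selected on the 9-point grid λ ∈ {−2, −1.5, …, 2} by
maximizing the profile log-likelihood of a simple genotype+treatment
fixed-effect model, with λ = 1 meaning "no transform" (λ is selected
once, before outlier removal); (3) the full mixed model is fitted and
observations whose Studentized deleted residuals exceed the two-sided
Bonferroni-corrected t critical value at α = 0.05 are removed, followed
by one refit — a single pass, not an iterate-to-exhaustion loop; (4)
random terms are backward-eliminated by REML likelihood-ratio tests at
α = 0.05, by default against the boundary-corrected ½χ²₀ + ½χ²₁ mixture
reference (a flag restores plain χ²₁); (5) cell-mean BLUEs are
back-transformed through the inverse Box–Cox map and multiplied by the
stored median.

Residual diagnostics use marginal residuals r = y − Xβ̂ studentized by
the diagonal of V̂ − XΦX̂', with the externally deleted correction
t_i = r_i·√((n−p−1)/(n−p−r_i²)) applied on top. This is a first-order
approximation to true leave-one-out studentization; it is exact for
ordinary regression and accurate for the mild dependence the trial's
variance components induce.

Fixed-effect F tests use the Kenward–Roger small-sample method: the Wald
statistic for a marginal-mean contrast is rescaled and referred to an
F(q, m) reference whose scale and denominator df are obtained by
matching the first two moments, using the inverse expected REML
information as the variance-component covariance. On balanced designs
this reproduces the classical ANOVA F and its stratum df exactly (a
property the test suite checks against a method-of-moments oracle).
Contrasts are built over the genotypes whose cells are all observed.

Repeatability uses the all-random reformulation (every design term
random around a fixed grand mean):

    r = σ̂²_g / (σ̂²_g + σ̂²_gi/n_irg + σ̂²_ε/n_plot),

with n_irg and n_plot the harmonic means of treatments and plots
observed per genotype. Its standard error is first-order delta method on
the variance-component covariance (inverse expected information). Wald
intervals for variance components are formed on the log scale, which
respects positivity and is considerably better calibrated than the raw
scale at these replication levels.

## Stress-response statistics

Missing BLUEs are imputed by k-nearest neighbours (default k = 10):
Euclidean distance on standardized traits over the mutually observed
entries, rescaled to the full trait count, with Gaussian kernel weights
exp(−d). PCA is an SVD of the log10-transformed, centered, scaled
matrix; nonpositive values entering log10 are floored at half the
trait's smallest positive value with a logged count, and zero-variance
traits are dropped under scaling. Cross-year integration multiplies each
value by median(trait, all years)/median(trait, this year), after which
within-year medians coincide exactly; hierarchical clustering uses
d = 1 − Pearson r with complete linkage (scipy's deterministic
agglomeration order).

The volcano classification works on non-log-transformed BLUEs: fold
change is mean(WL)/mean(WW) over the 22 accessions; significance is the
two-sided Mann–Whitney U test — exact by enumeration when the pooled
sample is ≤ 12 without ties, otherwise the tie- and continuity-corrected
normal approximation (the relevant case at n = 22 per group) — with
Benjamini–Hochberg control at FDR 0.05. A metabolite is a *decrease*
when p_adj < 0.05 and FC < 0.5, an *increase* when p_adj < 0.05 and
FC > 2. Class summaries count decreases/increases per main class and
subclass and report the mean ± SD fold change per category.

## Vegetation indices

All indices are computed at exact 1-nm bands: NDVI = (R820−R670)/
(R820+R670), PRI = (R531−R570)/(R531+R570), sPRI = (PRI+1)/2. Two
indices have conflicting printed and literature forms, so both are
implemented as explicit modes: CRI defaults to the ratio R550/R510 (the
algebraic value of the reciprocal-quotient expression, and the reading
consistent with typical leaf values around 2.0–2.4), with the Gitelson
reciprocal difference 1/R510 − 1/R550 as an alternative; WI defaults to
the ratio R900/R970 — the only reading under which WI/NDVI lands near
the characteristic 1.2–1.3 of green leaves — with the difference form
R900−R970 as an alternative. Every index except the WI-difference mode
is invariant to multiplying the whole spectrum by a constant. A `mode`
column records the conventions in every output table. Higher WI/NDVI
indicates lower leaf water content.

## Spectral regression

Each metabolite is regressed separately on the 2151-band spectrum with
PLS1. Components are extracted by the sequential covariance-maximizing
(NIPALS) scheme with X-deflation; X and y are mean-centered only (no
per-band autoscaling, the convention of the standard chemometric
software family; a flag is unnecessary because the caller can scale X
beforehand). One training pass yields the nested coefficient vectors for
every factor count, so leave-one-out RMSECV over A ∈ {0..12} costs n
fits, not 13n. A* minimizes RMSECV with ties broken toward smaller A;
A* = 0 is the intercept-only model and marks the metabolite "not
estimated". The full-dataset model reports R² = 1 − RSS/TSS.

Prediction uses a 4-fold cross-validation: samples are split at random
without replacement into four groups (unstratified by default, matching
a simple random subdivision; a stratified option exists); each submodel
re-selects its own A by LOO on its 33 training samples, so no held-out
information leaks into factor selection. Q²_fold = 1 − PRESS/TSS with
TSS taken about the *training* mean, which makes the mean predictor
score exactly 0. The reported Q² is the mean of the four fold values
(a pooled-PRESS variant is also emitted). A metabolite is "predicted"
iff all four submodels used ≥ 1 factor with non-negative Q². A strict
mode computing −PRESS/TSS (always ≤ 0) exists for comparison but is not
the default, since a sign-eligible predictability measure requires the
1−PRESS/TSS form.

Wavelength importance ranks the 2151 bands by |β_PLS| per metabolite
(rank 1 = largest; ties, which arise only in degenerate coefficient
vectors, break by ascending wavelength). The top-10% set is the
floor(0.10·2151) = 215 lowest ranks; selection-frequency histograms use
50-nm bins. Class-level curves average ranks over the metabolites of a
main class. The discrimination analysis runs the standard PCA on the
pooled held-out predictions of the metabolites with Q² above 0.5 and
summarizes treatment separation as the distance between treatment
centroids in the first two PCs divided by the mean within-treatment
RMS spread.

## Synthetic data: what it emulates and what it does not

`generate_trial` reproduces the design skeleton (randomized genotype
layout; 2 blocks of 11 and 11 columns per replicate).
`generate_metabolome` draws per-metabolite effects on the natural-log
scale — genotype SD 0.30, interaction SD 0.10, rep/block/column SDs
0.05, residual SD 0.20, log-baseline N(7, 1) — and exponentiates, so
intensities are log-normal and fold changes act multiplicatively, which
is what the pipeline's log transforms and ratio thresholds assume. Ten
percent of metabolites carry a planted irrigation response of
|log2 FC| = 2 (fold change 4 or ¼, alternating), the volcano-positive
ground truth. Missingness is MCAR at rate 0.05.

`generate_spectra` builds reflectance as a smooth green-leaf base curve
(red edge at 715 nm to a ~0.53 NIR plateau, green bump at 550 nm, gentle
SWIR decline) attenuated by multiplicative Gaussian absorption features:
pigment bands at 465/670 nm that are deeper in healthy WW leaves, water
bands at 970/1450/1940 nm scaling with a per-plot water content (1.0
under WW, 0.82 under WL, SD 0.03), and three metabolite-coupled bands
(520, 1730, 2300 nm) whose depths are linear in standardized latent
pools tied to specific simulated metabolites. The 520-nm band couples to
a stress-*decreasing* metabolite so the carotenoid index falls under
water limitation, as it does in drying leaves. Five leaves per plot get
iid Gaussian band noise (SD 0.005) and are clipped to (0, 1.2]. With
these defaults the treatment contrasts of NDVI (lower under WL), CRI
(lower under WL) and WI/NDVI (higher under WL) all point in the
physiologically expected directions.

The generator is *not* a radiative-transfer model: features are
Gaussian, noise is band-independent, and canopy/illumination geometry is
absent. Passing tests therefore demonstrate that the pipeline recovers
planted structure under the model's own assumptions (log-normal
intensities, linear depth–pool coupling), not that it would achieve the
same accuracy on field spectra.

`generate_coupled_dataset` isolates the spectra→metabolite regression:
n = 44 samples (the size of a genotype×treatment BLUE table), one
standardized response, coupled bands at 520/1450/1930 nm with depth
slopes (0.30, 0.04, 0.045) chosen to equalize the *effective* amplitude
base(λ)·slope across the VIS/SWIR (VIS base reflectance is ~4× lower
than the SWIR plateau). The band noise SD is calibrated analytically to
a target predictive R² (default 0.8) using the finite-sample formula
R²(n) ≈ [S/(S+σ²)]·[nS/(nS+pσ²)], S = ‖dm/dy‖²: the first factor is the
infinite-sample limit of the best linear read-out, the second the
attenuation from estimating a p ≫ n weight vector from n samples. The
infinite-sample definition alone would make the task impossible at
n = 44 (the oracle read-out pools all 2151 bands, which finite samples
cannot learn), so the finite-sample definition is the one under which a
"true R² of 0.8" is a meaningful statement about this study size.

## Problem sizes and numerical choices

Default sizes are desk-scale stand-ins chosen so each analysis stage is
exercised with realistic structure: 60 metabolites per year (the field
study has hundreds; 60 keeps two full pipeline years to a few minutes
while leaving ~6 planted responders), 2 simulated years, 50 generator
seeds for the regression-recovery study, and 200 simulated traits for
the variance-component coverage study. The pipeline's PLSR stage models
the treatment-significant metabolites (raw Mann–Whitney p < 0.05), which
is also the starting set for the volcano and discrimination analyses.
The spectral predictor matrix for PLSR is the genotype×treatment cell
mean of the plot spectra per band — the fixed-effect estimate when
design variance components are negligible — rather than 2151 separate
REML fits; the full mixed-model path is exercised by every metabolite
and vegetation index.

Numerical details: REML optimization tolerance ftol = 1e-14 (tight
enough that balanced-design estimates agree with closed-form ANOVA
method-of-moments to ~1e-6); variance ratios below 1e-10 are snapped to
the boundary; exact-fit quadratic forms are clamped at 1e-300 so
noiseless inputs degrade gracefully; NIPALS stops extracting when the
residual covariance falls below 1e-12 of its initial scale and pads the
RMSECV curve with the largest valid model. Reflectance outside [0, 1.5]
warns rather than errors (white-reference artifacts can push measured
reflectance slightly above 1).

## Known limitations

* The outlier pass removes all flagged observations at once and refits
  once; masked multiple outliers could survive.
* Wald/delta-method uncertainty for variance components and
  repeatability relies on asymptotic normality; with 4–8 levels per
  random term the log-scale intervals are approximate.
* Kenward–Roger df are computed from the expected (not observed)
  information; the two differ only in strongly unbalanced data.
* The k-NN imputer is O(n²·m) and intended for BLUE-sized tables
  (tens of samples), not raw feature matrices.
* Cross-year normalization assumes the shared metabolites were measured
  on ratio-comparable scales in both years; it corrects medians only.
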