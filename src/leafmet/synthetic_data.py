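"""Synthetic field-trial generator with known ground truth.

Emulates the study design the analysis pipeline targets: a panel of 22
cotton genotypes grown under well-watered (WW) and water-limited (WL)
irrigation in a randomized incomplete block design with two replicates
per treatment (88 plots), phenotyped for leaf metabolite intensities and
for leaf hyperspectral reflectance (350–2500 nm, five leaves per plot).

Three linked generators share one :class:`SimConfig`:

* :func:`generate_trial` — the plot-level factor structure plus all true
  effect draws (:class:`GroundTruth`);
* :func:`generate_metabolome` — per-plot metabolite intensities.  Effects
  act additively on the natural-log scale (so multiplicatively on
  intensities); a configured fraction of metabolites carries a planted
  |log2 fold change| ≥ 1 irrigation response (the volcano-positive set);
  a fraction of cells is set missing completely at random;
* :func:`generate_spectra` — per-leaf reflectance built as a smooth
  green-leaf base curve attenuated by multiplicative Gaussian absorption
  features.  Water bands (970/1450/1940 nm) are deeper under WW (higher
  leaf water content); chlorophyll and carotenoid features are deeper
  under WW; selected features are depth-coupled to latent metabolite
  pools so the chemistry signal is recoverable by regression on spectra.

:func:`generate_coupled_dataset` is a smaller, analytically calibrated
generator used to study the spectra→metabolite regression in isolation:
one standardized response, three absorption features whose depths are
linear in the response, and band noise sized to a target population R².
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import WAVELENGTH_GRID, SpectraTable

__all__ = [
    "SimConfig",
    "AbsorptionFeature",
    "GroundTruth",
    "CoupledDataset",
    "generate_trial",
    "generate_metabolome",
    "generate_spectra",
    "generate_coupled_dataset",
    "base_leaf_curve",
    "leaf_to_plot",
]

LN2 = float(np.log(2.0))


@dataclasses.dataclass(frozen=True)
class AbsorptionFeature:
    """One multiplicative Gaussian absorption feature in the leaf spectrum.

    depth(plot) = base_depth * water-coupling * treatment factor
                  + pool_coef * pool_value(plot), clipped to [0, 0.97].
    """

    center_nm: float
    width_nm: float
    base_depth: float
    pool: int | None = None        # index into the latent pool list, or None
    pool_coef: float = 0.0
    wl_mult: float = 1.0           # depth multiplier under water limitation
    water_coupled: bool = False    # scales with per-plot water content


def _default_features() -> tuple[AbsorptionFeature, ...]:
    return (
        # pigment features: deeper in healthy WW leaves
        AbsorptionFeature(465.0, 30.0, 0.55, wl_mult=0.80),           # carotenoid/blue
        AbsorptionFeature(670.0, 45.0, 0.45, wl_mult=0.85),           # chlorophyll red
        # water absorption bands: scale with leaf water content
        AbsorptionFeature(970.0, 40.0, 0.10, water_coupled=True),
        AbsorptionFeature(1450.0, 45.0, 0.55, water_coupled=True),
        AbsorptionFeature(1940.0, 60.0, 0.75, water_coupled=True),
        # metabolite-coupled features; pool 1 is a stress-decreasing
        # metabolite, so the 520 nm depth tracks carotenoid-like chemistry
        AbsorptionFeature(520.0, 22.0, 0.25, pool=1, pool_coef=0.06),
        AbsorptionFeature(1730.0, 45.0, 0.28, pool=0, pool_coef=0.07),  # C–H lipid
        AbsorptionFeature(2300.0, 40.0, 0.22, pool=2, pool_coef=0.06),
    )


@dataclasses.dataclass
class SimConfig:
    """Trial dimensions and effect sizes for the synthetic generator."""

    n_genotypes: int = 22
    n_treatments: int = 2          # WW, WL
    n_reps: int = 2
    blocks_per_rep: int = 2
    columns_per_rep: int = 11
    n_metabolites: int = 60
    missing_rate: float = 0.05
    seed: int = 0
    # log-scale (natural log) effect sizes for metabolite intensities
    genotype_sd: float = 0.30
    interaction_sd: float = 0.10
    rep_sd: float = 0.05
    block_sd: float = 0.05
    column_sd: float = 0.05
    residual_sd: float = 0.20
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 1.0
    # planted irrigation response: this fraction of metabolites gets
    # |log2 FC| = responsive_log2fc (alternating increase/decrease)
    frac_responsive: float = 0.10
    responsive_log2fc: float = 2.0
    # spectral model
    features: tuple[AbsorptionFeature, ...] = dataclasses.field(
        default_factory=_default_features
    )
    n_pools: int = 3
    wl_water_content: float = 0.82  # WW water content is 1.0
    water_content_sd: float = 0.03
    leaf_noise_sd: float = 0.005
    n_leaves_per_plot: int = 5

    def __post_init__(self) -> None:
        sds = (self.genotype_sd, self.interaction_sd, self.rep_sd,
               self.block_sd, self.column_sd, self.residual_sd,
               self.water_content_sd, self.leaf_noise_sd)
        if any(s < 0 for s in sds):
            raise ValueError("all effect SDs must be nonnegative")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        for f in self.features:
            if not 350.0 <= f.center_nm <= 2500.0:
                raise ValueError(f"feature center {f.center_nm} outside 350-2500 nm")
        if self.n_genotypes % self.blocks_per_rep:
            raise ValueError("blocks_per_rep must divide the plots per replicate")

    @property
    def treatments(self) -> tuple[str, ...]:
        return ("WW", "WL")[: self.n_treatments]

    @property
    def n_plots(self) -> int:
        return self.n_genotypes * self.n_treatments * self.n_reps


@dataclasses.dataclass
class GroundTruth:
    """Every random draw behind one simulated trial, for parameter recovery."""

    config: SimConfig
    mu: np.ndarray                    # (n_metabolites,) baseline log intensity
    genotype_effects: np.ndarray      # (n_metabolites, n_genotypes)
    treatment_log2fc: np.ndarray      # (n_metabolites,) WL vs WW
    interaction_effects: np.ndarray   # (n_metabolites, n_genotypes, n_treatments)
    rep_effects: np.ndarray           # (n_metabolites, n_treatments, n_reps)
    block_effects: np.ndarray         # (n_met, n_trt, n_reps, blocks_per_rep)
    column_effects: np.ndarray        # (n_met, n_trt, n_reps, columns_per_rep)
    responsive: np.ndarray            # bool mask over metabolites
    pool_metabolites: np.ndarray      # metabolite index per latent pool
    water_content: np.ndarray | None = None  # per plot, filled by generate_spectra
    log_intensity: np.ndarray | None = None  # (n_plots, n_met), pre-missingness
    pools: np.ndarray | None = None          # (n_plots, n_pools) standardized

    @property
    def variance_components(self) -> dict[str, float]:
        c = self.config
        return {
            "genotype": c.genotype_sd**2,
            "interaction": c.interaction_sd**2,
            "rep": c.rep_sd**2,
            "block": c.block_sd**2,
            "column": c.column_sd**2,
            "residual": c.residual_sd**2,
        }


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def generate_trial(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Build the randomized incomplete block design and draw all true effects.

    Returns the plot-level design table (plot, genotype, treatment, rep,
    block, column) and the :class:`GroundTruth` carrying every effect draw.
    Identical ``(config, seed)`` regenerate the same design exactly.
    """
    c = config
    rng = _rng(c, 0)
    rows = []
    plot_no = 0
    for j, trt in enumerate(c.treatments):
        for k in range(c.n_reps):
            geno_order = rng.permutation(c.n_genotypes)
            plots_per_block = c.n_genotypes // c.blocks_per_rep
            for pos, g in enumerate(geno_order):
                plot_no += 1
                rows.append({
                    "plot": f"P{plot_no:03d}",
                    "genotype": f"G{g + 1:02d}",
                    "treatment": trt,
                    "rep": f"R{k + 1}",
                    "block": f"B{pos // plots_per_block + 1}",
                    "column": f"C{pos % c.columns_per_rep + 1}",
                })
    design = pd.DataFrame(rows).set_index("plot")

    m, g, t = c.n_metabolites, c.n_genotypes, c.n_treatments
    n_resp = int(round(c.frac_responsive * m))
    responsive = np.zeros(m, dtype=bool)
    responsive[:n_resp] = True
    signs = np.where(np.arange(n_resp) % 2 == 0, 1.0, -1.0)
    log2fc = np.zeros(m)
    log2fc[:n_resp] = signs * c.responsive_log2fc

    truth = GroundTruth(
        config=c,
        mu=rng.normal(c.baseline_log_mean, c.baseline_log_sd, size=m),
        genotype_effects=rng.normal(0.0, c.genotype_sd, size=(m, g)),
        treatment_log2fc=log2fc,
        interaction_effects=rng.normal(0.0, c.interaction_sd, size=(m, g, t)),
        rep_effects=rng.normal(0.0, c.rep_sd, size=(m, t, c.n_reps)),
        block_effects=rng.normal(0.0, c.block_sd, size=(m, t, c.n_reps, c.blocks_per_rep)),
        column_effects=rng.normal(0.0, c.column_sd, size=(m, t, c.n_reps, c.columns_per_rep)),
        responsive=responsive,
        pool_metabolites=np.arange(min(c.n_pools, m)) % m,
    )
    return design, truth


def _metabolite_codes(design: pd.DataFrame, config: SimConfig):
    g_idx = design["genotype"].str.slice(1).astype(int).to_numpy() - 1
    t_idx = np.array([config.treatments.index(t) for t in design["treatment"]])
    r_idx = design["rep"].str.slice(1).astype(int).to_numpy() - 1
    b_idx = design["block"].str.slice(1).astype(int).to_numpy() - 1
    c_idx = design["column"].str.slice(1).astype(int).to_numpy() - 1
    return g_idx, t_idx, r_idx, b_idx, c_idx


def generate_metabolome(
    design: pd.DataFrame, truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """Per-plot metabolite intensities (plots × metabolites, NaN = missing).

    For metabolite *t* the log intensity of plot (i genotype, j treatment,
    k rep, l block, m column) is

        mu_t + g_ti + ln(2)·log2FC_t·[j = WL] + (g×irg)_tij
             + rep_tjk + block_tjkl + column_tjkm + eps,

    and the reported intensity is its exponential (log-normal noise: the
    downstream pipeline log-transforms, and fold changes are ratio-scaled).
    """
    c = config
    g_idx, t_idx, r_idx, b_idx, c_idx = _metabolite_codes(design, c)
    rng = _rng(c, 1)
    n = len(design)
    m = c.n_metabolites

    log_int = (
        truth.mu[None, :]
        + truth.genotype_effects[:, g_idx].T
        + LN2 * truth.treatment_log2fc[None, :] * (t_idx == 1)[:, None]
        + truth.interaction_effects[:, g_idx, t_idx].T
        + truth.rep_effects[:, t_idx, r_idx].T
        + truth.block_effects[:, t_idx, r_idx, b_idx].T
        + truth.column_effects[:, t_idx, r_idx, c_idx].T
        + rng.normal(0.0, c.residual_sd, size=(n, m))
    )
    truth.log_intensity = log_int

    intensities = np.exp(log_int)
    if c.missing_rate > 0:
        mask = rng.random(size=(n, m)) < c.missing_rate
        intensities = np.where(mask, np.nan, intensities)
    return pd.DataFrame(
        intensities, index=design.index,
        columns=[f"met{j + 1:03d}" for j in range(m)],
    )


def base_leaf_curve(wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Smooth green-leaf reflectance backbone before absorption features.

    Low visible reflectance with a green bump near 550 nm, a red edge at
    ~715 nm to a NIR plateau of ~0.53, and a gentle SWIR decline.
    """
    lam = WAVELENGTH_GRID.astype(float) if wavelengths is None else np.asarray(wavelengths, float)
    red_edge = 1.0 / (1.0 + np.exp(-(lam - 715.0) / 22.0))
    swir_decline = 1.0 / (1.0 + np.exp(-(lam - 1800.0) / 250.0))
    green_bump = 0.07 * np.exp(-((lam - 550.0) ** 2) / (2 * 35.0**2))
    return 0.08 + 0.45 * red_edge + green_bump - 0.15 * swir_decline


def _feature_depths(
    features: Sequence[AbsorptionFeature],
    is_wl: np.ndarray,
    water: np.ndarray,
    pools: np.ndarray,
) -> np.ndarray:
    """Per (plot, feature) absorption depths, clipped to [0, 0.97]."""
    n = is_wl.shape[0]
    depths = np.empty((n, len(features)))
    for k, f in enumerate(features):
        d = np.full(n, f.base_depth)
        if f.water_coupled:
            d = d * water
        if f.wl_mult != 1.0:
            d = d * np.where(is_wl, f.wl_mult, 1.0)
        if f.pool is not None and pools.size:
            d = d + f.pool_coef * pools[:, f.pool]
        depths[:, k] = np.clip(d, 0.0, 0.97)
    return depths


def _apply_features(
    base: np.ndarray,
    features: Sequence[AbsorptionFeature],
    depths: np.ndarray,
    lam: np.ndarray,
) -> np.ndarray:
    """reflectance(λ) = base(λ) · Π_k [1 − depth_k · exp(−(λ−c_k)²/2w_k²)]."""
    refl = np.tile(base, (depths.shape[0], 1))
    for k, f in enumerate(features):
        shape = np.exp(-((lam - f.center_nm) ** 2) / (2 * f.width_nm**2))
        refl *= 1.0 - depths[:, k, None] * shape[None, :]
    return refl


def generate_spectra(
    design: pd.DataFrame, truth: GroundTruth, config: SimConfig
) -> SpectraTable:
    """Leaf-level reflectance spectra (n_leaves_per_plot per plot).

    Latent pools are the standardized log intensities of the configured
    pool metabolites (pre-missingness); water content is 1.0 under WW and
    ``wl_water_content`` under WL plus per-plot noise.  Values are clipped
    to (0, 1.2].  Leaf sample ids are ``<plot>_L<k>``.
    """
    c = config
    if truth.log_intensity is None:
        raise ValueError("generate_metabolome must run before generate_spectra")
    rng = _rng(c, 2)
    lam = WAVELENGTH_GRID.astype(float)
    is_wl = (design["treatment"] == "WL").to_numpy()
    n = len(design)

    water = np.where(is_wl, c.wl_water_content, 1.0) + rng.normal(0, c.water_content_sd, n)
    water = np.clip(water, 0.0, None)
    pool_log = truth.log_intensity[:, truth.pool_metabolites]
    sd = pool_log.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    pools = (pool_log - pool_log.mean(axis=0)) / sd
    truth.water_content = water
    truth.pools = pools

    depths = _feature_depths(c.features, is_wl, water, pools)
    plot_refl = _apply_features(base_leaf_curve(lam), c.features, depths, lam)

    leaf_ids, leaf_rows = [], []
    for i, plot in enumerate(design.index):
        for leaf in range(c.n_leaves_per_plot):
            leaf_ids.append(f"{plot}_L{leaf + 1}")
            leaf_rows.append(plot_refl[i])
    leaves = np.asarray(leaf_rows) + rng.normal(0, c.leaf_noise_sd, (n * c.n_leaves_per_plot, lam.size))
    leaves = np.clip(leaves, 1e-6, 1.2)
    return SpectraTable(pd.DataFrame(leaves, index=leaf_ids, columns=WAVELENGTH_GRID))


def leaf_to_plot(leaf_spectra: SpectraTable) -> dict[str, str]:
    """Recover the leaf→plot grouping from ``<plot>_L<k>`` sample ids."""
    return {s: s.rsplit("_L", 1)[0] for s in leaf_spectra.sample_ids}


_MAIN_CLASSES = (
    ("neutral lipids", ("TAG", "DAG", "MAG")),
    ("polar lipids", ("PCh", "PE", "PI")),
    ("terpenoids", ("triterpenoid", "sesquiterpenoid")),
    ("carbohydrates and conjugates", ("sugar acid", "sugar alcohol")),
    ("amino acids and peptides", ("amino acid", "dipeptide")),
)


def generate_annotation(config: SimConfig) -> pd.DataFrame:
    """Synthetic metabolite annotation (platform, class, subclass, InChIKey).

    Classes cycle through the lipid/terpenoid/carbohydrate/amino-acid
    groups the class-level summaries report on; the InChIKeys are
    synthetic placeholder identifiers, present for every metabolite so
    all simulated compounds pass the annotation filter.
    """
    rows = []
    for j in range(config.n_metabolites):
        main, subs = _MAIN_CLASSES[j % len(_MAIN_CLASSES)]
        rows.append({
            "trait_id": f"met{j + 1:03d}",
            "platform": "GC" if j % 7 == 0 else "LC",
            "main_class": main,
            "subclass": subs[j % len(subs)],
            "inchikey": f"SYNTHKEY{j + 1:05d}-SIMULATEDXX-N",
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Calibrated single-response generator for the regression analyses


@dataclasses.dataclass
class CoupledDataset:
    """One standardized response coupled to known absorption bands."""

    spectra: SpectraTable            # plot-level, n samples
    y: pd.Series                     # standardized response per sample
    treatment: pd.Series             # WW/WL labels (balanced)
    coupled_centers: tuple[float, ...]
    true_r2: float
    noise_sd: float


def generate_coupled_dataset(
    n_samples: int = 44,
    true_r2: float = 0.8,
    seed: int = 0,
    centers: tuple[float, ...] = (520.0, 1450.0, 1930.0),
    widths: tuple[float, ...] = (30.0, 45.0, 55.0),
    # slopes equalize the *effective* band amplitude base(λ)·slope: the
    # VIS base reflectance is ~4x lower than the SWIR plateau
    depth_slopes: tuple[float, ...] = (0.30, 0.04, 0.045),
) -> CoupledDataset:
    """Spectra whose planted-band depths are linear in a N(0,1) response.

    The band noise SD is calibrated analytically.  With reflectance
    x_λ = m_λ(y) + ε_λ, ε iid N(0, σ²) over p bands, and s = dm/dy
    evaluated at y = 0, a linear read-out whose weight vector is itself
    estimated from n training samples attains expected predictive

        R²(n) ≈ [S/(S + σ²)] · [nS/(nS + pσ²)],   S = ‖s‖²,

    where the first factor is the infinite-sample (oracle-direction)
    limit and the second is the attenuation from weight-estimation noise
    (the oracle direction pools p ≫ n bands, which finite samples cannot
    learn exactly).  σ is the root of R²(n) = ``true_r2`` at the
    dataset's own n.  Context features (pigments and the 970/1940 nm
    water bands, with a small treatment effect on water content) are
    present but uncoupled to y, providing structured background
    variation.
    """
    if not 0.0 < true_r2 < 1.0:
        raise ValueError("true_r2 must be in (0, 1)")
    rng = np.random.default_rng([int(seed), 3])
    lam = WAVELENGTH_GRID.astype(float)
    y = rng.normal(size=n_samples)
    y = (y - y.mean()) / y.std(ddof=0)

    treatment = np.array(["WW", "WL"])[np.arange(n_samples) % 2]
    is_wl = treatment == "WL"
    water = np.where(is_wl, 0.88, 1.0) + rng.normal(0, 0.02, n_samples)

    context = [
        AbsorptionFeature(490.0, 35.0, 0.55, wl_mult=0.92),
        AbsorptionFeature(670.0, 45.0, 0.45, wl_mult=0.92),
        AbsorptionFeature(970.0, 40.0, 0.10, water_coupled=True),
    ]
    coupled = [
        AbsorptionFeature(c0, w0, 0.30, pool=0, pool_coef=b0)
        for c0, w0, b0 in zip(centers, widths, depth_slopes)
    ]
    features = context + coupled

    def clean(yv: np.ndarray, wat: np.ndarray, wl: np.ndarray) -> np.ndarray:
        pools = yv[:, None]
        depths = _feature_depths(features, wl, wat, pools)
        return _apply_features(base_leaf_curve(lam), features, depths, lam)

    # sensitivity of the mean spectrum to y, at mean water content
    w0 = np.full(1, water.mean())
    f0 = np.zeros(1, dtype=bool)
    eps = 1e-4
    s = (clean(np.array([eps]), w0, f0) - clean(np.array([-eps]), w0, f0)) / (2 * eps)
    S = float(np.linalg.norm(s)) ** 2
    # solve r·(S+u)(nS+pu) = nS² for u = σ²  (see docstring)
    r, p_bands = true_r2, float(lam.size)
    a = r * p_bands
    b = r * S * (p_bands + n_samples)
    c = (r - 1.0) * n_samples * S**2
    u = (-b + np.sqrt(b**2 - 4 * a * c)) / (2 * a)
    noise_sd = float(np.sqrt(u))

    refl = clean(y, water, is_wl) + rng.normal(0, noise_sd, (n_samples, lam.size))
    refl = np.clip(refl, 1e-6, 1.2)
    ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    return CoupledDataset(
        spectra=SpectraTable(pd.DataFrame(refl, index=ids, columns=WAVELENGTH_GRID)),
        y=pd.Series(y, index=ids, name="response"),
        treatment=pd.Series(treatment, index=ids, name="treatment"),
        coupled_centers=tuple(float(c0) for c0 in centers),
        true_r2=true_r2,
        noise_sd=float(noise_sd),
    )
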