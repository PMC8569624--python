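"""Per-trait field-trial preprocessing: REML mixed models and BLUEs.

Each trait (metabolite intensity, fiber trait, vegetation index, or
single waveband) measured on the 88-plot trial is processed per year:

1. median rescale (metabolites) — divide by the within-year median;
2. Box–Cox selection — λ on the grid −2..+2 step 0.5 maximizing the
   profile log-likelihood of a genotype+treatment fixed-effect model;
3. REML fit of the full mixed model

       y = μ + genotype + irg + genotype×irg            (fixed)
         + rep(irg) + block(rep×irg) + column(rep×irg)  (random)
         + ε,

   with variance components constrained nonnegative;
4. outlier removal by Studentized deleted residuals (Bonferroni t) and
   one refit;
5. backward elimination of non-significant random terms by REML
   likelihood-ratio tests (α = 0.05, boundary-corrected ½χ²₀+½χ²₁
   reference by default);
6. BLUEs — one estimate per genotype×treatment cell, back-transformed
   through the inverse Box–Cox map and rescaled by the stored median;
7. repeatability r = σ²_g / (σ²_g + σ²_gi/n_irg + σ²_ε/n_plot) from the
   all-random reformulation, with a delta-method standard error.

The fixed part is parameterized by genotype×treatment cell means, which
makes every BLUE directly estimable; F tests for the main effects and
interaction use marginal-mean contrasts with Kenward–Roger denominator
degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "BOXCOX_GRID",
    "MixedModelSpec",
    "MixedModelFit",
    "BoxCoxResult",
    "RepeatabilityEstimate",
    "median_rescale",
    "boxcox_select",
    "fit_mixed_model",
    "detect_outliers",
    "backward_eliminate_random",
    "compute_blues",
    "repeatability",
    "fixed_effect_tests",
    "preprocess_trait",
    "preprocess_table",
]

BOXCOX_GRID = np.arange(-2.0, 2.0 + 1e-9, 0.5)

RANDOM_TERM_COLUMNS = {
    "rep": ("treatment", "rep"),
    "block": ("treatment", "rep", "block"),
    "column": ("treatment", "rep", "column"),
}


# --------------------------------------------------------------------------
# median rescale


def median_rescale(values: np.ndarray | pd.Series, direction: str = "forward",
                   median: float | None = None) -> tuple[np.ndarray, float]:
    """Divide a trait vector by its median (forward) or undo it (back).

    Returns ``(rescaled_values, median)``; the median returned by the
    forward pass is what the back pass needs.
    """
    arr = np.asarray(values, dtype=float)
    if direction == "forward":
        finite = arr[np.isfinite(arr)]
        if finite.size == 0:
            raise ValueError("no non-missing values to compute a median")
        med = float(np.median(finite))
        if med == 0:
            raise ValueError("median is zero; cannot rescale")
        return arr / med, med
    if direction == "back":
        if median is None:
            raise ValueError("back transformation requires the stored median")
        return arr * median, float(median)
    raise ValueError(f"unknown direction {direction!r}")


# --------------------------------------------------------------------------
# Box–Cox selection


@dataclasses.dataclass
class BoxCoxResult:
    """Selected power transform with its forward and inverse maps."""

    lam: float
    transformed: bool
    profile_loglik: dict[float, float]

    def forward(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if np.any(y[np.isfinite(y)] <= 0):
            raise ValueError("Box–Cox requires positive values; shift the trait first")
        if self.lam == 0:
            return np.log(y)
        return (y**self.lam - 1.0) / self.lam

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.lam == 0:
            return np.exp(z)
        return np.power(self.lam * z + 1.0, 1.0 / self.lam)


def _fixed_cellmean_matrix(design: pd.DataFrame, columns: Sequence[str]) -> tuple[np.ndarray, list]:
    """Indicator matrix of the interaction of the given factor columns."""
    labels = design[list(columns)].astype(str).agg(":".join, axis=1)
    cats = pd.Categorical(labels)
    X = pd.get_dummies(cats, dtype=float).to_numpy()
    return X, list(cats.categories)


def boxcox_select(y: np.ndarray | pd.Series, design: pd.DataFrame) -> BoxCoxResult:
    """Pick λ on the 9-point grid by the Box–Cox profile log-likelihood.

    The working model is the simple fixed-effect linear model with
    genotype and treatment main effects.  ``transformed`` is False when
    λ = 1 is optimal (identity scale, up to a shift).
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    y, design = y[mask], design.loc[mask]
    if np.any(y <= 0):
        raise ValueError("Box–Cox requires positive values; shift the trait first")
    Xg, _ = _fixed_cellmean_matrix(design, ["genotype"])
    Xt, _ = _fixed_cellmean_matrix(design, ["treatment"])
    X = np.hstack([np.ones((len(y), 1)), Xg[:, 1:], Xt[:, 1:]])
    n = len(y)
    log_y_sum = float(np.log(y).sum())
    profile = {}
    for lam in BOXCOX_GRID:
        z = np.log(y) if lam == 0 else (y**lam - 1.0) / lam
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        rss = float(np.sum((z - X @ beta) ** 2))
        profile[float(lam)] = -0.5 * n * np.log(rss / n) + (lam - 1.0) * log_y_sum
    lam_best = max(profile, key=lambda k: profile[k])
    return BoxCoxResult(lam=lam_best, transformed=(lam_best != 1.0), profile_loglik=profile)


# --------------------------------------------------------------------------
# REML core


@dataclasses.dataclass
class MixedModelSpec:
    """Fixed genotype×irg cell means plus an eliminable set of random terms."""

    random_terms: tuple[str, ...] = ("rep", "block", "column")

    def without(self, term: str) -> "MixedModelSpec":
        return MixedModelSpec(tuple(t for t in self.random_terms if t != term))


@dataclasses.dataclass
class MixedModelFit:
    """One REML fit: variance components, cell-mean estimates, diagnostics."""

    design: pd.DataFrame
    y: np.ndarray
    spec: MixedModelSpec
    cells: list[str]                      # "genotype:treatment" labels
    beta: np.ndarray                      # GLS cell-mean estimates
    cov_beta: np.ndarray
    variance_components: dict[str, float]  # per random term + "residual"
    loglik: float                          # restricted log-likelihood
    residuals: np.ndarray                  # marginal residuals y − Xβ
    student_deleted: np.ndarray            # externally studentized residuals
    X: np.ndarray
    Z: dict[str, np.ndarray]
    vc_cov: np.ndarray | None = None       # cov of variance-component estimates

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def cell_estimates(self) -> pd.Series:
        return pd.Series(self.beta, index=self.cells, name="blue")


def _random_term_matrix(design: pd.DataFrame, term: str) -> np.ndarray:
    cols = RANDOM_TERM_COLUMNS[term]
    Z, _ = _fixed_cellmean_matrix(design, cols)
    return Z


def _neg2_reml(gamma: np.ndarray, y: np.ndarray, X: np.ndarray,
               Zs: list[np.ndarray]) -> tuple[float, dict]:
    """−2·(profiled restricted log-likelihood) up to an additive constant.

    gamma are variance ratios σ²_i/σ²_ε ≥ 0; σ²_ε is profiled out.
    """
    n, p = X.shape
    H = np.eye(n)
    for g, Z in zip(gamma, Zs):
        if g > 0:
            H += g * (Z @ Z.T)
    cF = linalg.cho_factor(H, lower=True)
    logdet_H = 2.0 * np.sum(np.log(np.diag(cF[0])))
    Hinv_X = linalg.cho_solve(cF, X)
    Hinv_y = linalg.cho_solve(cF, y)
    XtHX = X.T @ Hinv_X
    sign, logdet_XtHX = np.linalg.slogdet(XtHX)
    if sign <= 0:
        return np.inf, {}
    beta = np.linalg.solve(XtHX, X.T @ Hinv_y)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve(cF, r))
    # exact fits (noiseless data) leave a zero quadratic form; clamp so the
    # profiled criterion stays finite and sigma2 collapses to ~0
    quad = max(quad, 1e-300)
    crit = logdet_H + logdet_XtHX + (n - p) * np.log(quad)
    aux = {"beta": beta, "XtHX": XtHX, "quad": quad, "cho": cF, "H": H}
    return crit, aux


def _reml_optimize(y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray]) -> tuple[np.ndarray, dict]:
    if not Zs:
        _, aux = _neg2_reml(np.zeros(0), y, X, Zs)
        return np.zeros(0), aux
    k = len(Zs)
    best = None
    for start in (0.05, 0.5, 2.0):
        res = optimize.minimize(
            lambda g: _neg2_reml(g, y, X, Zs)[0],
            x0=np.full(k, start),
            method="L-BFGS-B",
            bounds=[(0.0, 1e6)] * k,
            options={"ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    gamma = np.clip(best.x, 0.0, None)
    gamma[gamma < 1e-10] = 0.0
    _, aux = _neg2_reml(gamma, y, X, Zs)
    return gamma, aux


def _restricted_loglik(crit_parts: dict, n: int, p: int) -> float:
    quad = crit_parts["quad"]
    sigma2 = quad / (n - p)
    H = crit_parts["H"]
    sign, logdet_H = np.linalg.slogdet(H)
    _, logdet_XtHX = np.linalg.slogdet(crit_parts["XtHX"])
    return -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                   + logdet_H + logdet_XtHX)


def _vc_expected_information(sig2: np.ndarray, X: np.ndarray,
                             Zs: list[np.ndarray]) -> np.ndarray:
    """Expected (Fisher) information for (σ²_1..σ²_k, σ²_ε) under REML."""
    n = X.shape[0]
    V = sig2[-1] * np.eye(n)
    for s, Z in zip(sig2[:-1], Zs):
        V += s * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.solve(XtVinvX, X.T @ Vinv)
    Vds = [Z @ Z.T for Z in Zs] + [np.eye(n)]
    k = len(Vds)
    info = np.empty((k, k))
    PV = [P @ Vi for Vi in Vds]
    for i in range(k):
        for j in range(i, k):
            info[i, j] = info[j, i] = 0.5 * np.trace(PV[i] @ PV[j])
    return info


def fit_mixed_model(design: pd.DataFrame, y: np.ndarray | pd.Series,
                    spec: MixedModelSpec | None = None,
                    compute_vc_cov: bool = False) -> MixedModelFit:
    """REML fit of the trial mixed model for one trait.

    ``design`` needs columns genotype, treatment, rep, block, column; the
    fixed part is the genotype×treatment cell-mean structure.  Missing
    responses are dropped.  Variance components are constrained ≥ 0.
    """
    spec = spec or MixedModelSpec()
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    y, design = y[mask], design.loc[mask]
    n = len(y)
    if n == 0:
        raise ValueError("no observations")

    X, cells = _fixed_cellmean_matrix(design, ["genotype", "treatment"])
    p = X.shape[1]
    Zs = [_random_term_matrix(design, t) for t in spec.random_terms]

    if p == n:
        # one observation per observed cell: the fixed structure is
        # saturated and no residual variance is estimable
        warnings.warn("saturated fixed-effect structure: one observation per "
                      "genotype×treatment cell; residual variance set to 0",
                      stacklevel=2)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return MixedModelFit(
            design=design, y=y, spec=spec, cells=cells, beta=beta,
            cov_beta=np.zeros((p, p)),
            variance_components={**{t: 0.0 for t in spec.random_terms},
                                 "residual": 0.0},
            loglik=np.nan, residuals=y - X @ beta,
            student_deleted=np.zeros(n), X=X,
            Z={t: Z for t, Z in zip(spec.random_terms, Zs)}, vc_cov=None,
        )

    gamma, aux = _reml_optimize(y, X, Zs)
    sigma2_eps = aux["quad"] / (n - p)
    vcs = {t: float(g * sigma2_eps) for t, g in zip(spec.random_terms, gamma)}
    vcs["residual"] = float(sigma2_eps)
    beta = aux["beta"]
    cov_beta = sigma2_eps * np.linalg.inv(aux["XtHX"])
    loglik = _restricted_loglik(aux, n, p)

    # marginal residuals, studentized with the externally deleted correction
    resid = y - X @ beta
    V = sigma2_eps * aux["H"]
    var_resid = np.clip(np.diag(V - X @ cov_beta @ X.T), 1e-12, None)
    r_int = resid / np.sqrt(var_resid)
    dof = n - p - 1
    if dof > 0:
        denom = np.clip(n - p - r_int**2, 1e-8, None)
        t_ext = r_int * np.sqrt(dof / denom)
    else:
        t_ext = np.zeros_like(r_int)

    vc_cov = None
    if compute_vc_cov:
        sig2 = np.array([vcs[t] for t in spec.random_terms] + [sigma2_eps])
        info = _vc_expected_information(sig2, X, Zs)
        vc_cov = np.linalg.pinv(info)

    return MixedModelFit(
        design=design, y=y, spec=spec, cells=cells, beta=beta,
        cov_beta=cov_beta, variance_components=vcs, loglik=loglik,
        residuals=resid, student_deleted=t_ext, X=X,
        Z={t: Z for t, Z in zip(spec.random_terms, Zs)}, vc_cov=vc_cov,
    )


def detect_outliers(fit: MixedModelFit, alpha: float = 0.05) -> np.ndarray:
    """Flag observations by Studentized deleted residuals.

    Two-sided t threshold at level ``alpha`` with Bonferroni correction
    across the n observations; returns a boolean mask aligned with the
    fit's observations.
    """
    n = fit.n_obs
    dof = n - fit.X.shape[1] - 1
    if n < 2 or dof < 1:
        warnings.warn("too few observations for outlier detection", stacklevel=2)
        return np.zeros(n, dtype=bool)
    crit = stats.t.ppf(1.0 - alpha / (2.0 * n), dof)
    return np.abs(fit.student_deleted) > crit


def lrt_random_term(full: MixedModelFit, reduced: MixedModelFit,
                    boundary_mixture: bool = True) -> float:
    """REML likelihood-ratio p-value for dropping one variance component.

    Uses the ½χ²₀ + ½χ²₁ mixture reference by default (the tested value
    σ² = 0 sits on the parameter boundary); set ``boundary_mixture=False``
    for the plain χ²₁ reference.
    """
    lr = 2.0 * (full.loglik - reduced.loglik)
    if lr <= 0:
        return 1.0
    p = stats.chi2.sf(lr, df=1)
    return 0.5 * p if boundary_mixture else p


def backward_eliminate_random(design: pd.DataFrame, y: np.ndarray | pd.Series,
                              spec: MixedModelSpec | None = None,
                              alpha: float = 0.05,
                              boundary_mixture: bool = True) -> MixedModelFit:
    """Drop random terms that fail their REML LRT at level ``alpha``.

    Iteratively removes the least significant random term (largest LRT
    p ≥ α) and refits, until every remaining term is significant.  Fixed
    terms are never touched.
    """
    spec = spec or MixedModelSpec()
    fit = fit_mixed_model(design, y, spec)
    while fit.spec.random_terms:
        pvals = {}
        for term in fit.spec.random_terms:
            reduced = fit_mixed_model(design, y, fit.spec.without(term))
            pvals[term] = lrt_random_term(fit, reduced, boundary_mixture)
        worst = max(pvals, key=lambda t: pvals[t])
        if pvals[worst] < alpha:
            break
        fit = fit_mixed_model(design, y, fit.spec.without(worst))
    return fit


# --------------------------------------------------------------------------
# BLUEs


def compute_blues(fit: MixedModelFit, boxcox: BoxCoxResult | None = None,
                  median: float | None = None) -> pd.DataFrame:
    """One BLUE per genotype×treatment cell, on the original trait scale.

    Cell-mean estimates are back-transformed through the inverse Box–Cox
    map (when a transform was selected) and multiplied by the stored
    median.  Cells emptied by outlier removal come back as NaN.
    """
    est = fit.cell_estimates()
    genotypes = sorted(fit.design["genotype"].unique())
    treatments = list(dict.fromkeys(fit.design["treatment"]))
    rows = []
    for g in genotypes:
        for t in treatments:
            key = f"{g}:{t}"
            if key in est.index:
                val = float(est[key])
            else:
                warnings.warn(f"cell {key} not estimable (no observations)", stacklevel=2)
                val = np.nan
            rows.append({"genotype": g, "treatment": t, "blue": val})
    table = pd.DataFrame(rows)
    vals = table["blue"].to_numpy()
    if boxcox is not None and boxcox.transformed:
        with np.errstate(invalid="ignore"):
            vals = boxcox.inverse(vals)
    if median is not None:
        vals, _ = median_rescale(vals, "back", median)
    table["blue"] = vals
    return table


# --------------------------------------------------------------------------
# repeatability


@dataclasses.dataclass
class RepeatabilityEstimate:
    r: float
    se: float
    n_irg: float
    n_plot: float
    variance_components: dict[str, float]


def _harmonic_mean(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    return len(counts) / np.sum(1.0 / counts)


def repeatability_from_components(sig_g: float, sig_gi: float, sig_eps: float,
                                  n_irg: float, n_plot: float,
                                  vc_cov: np.ndarray | None = None) -> tuple[float, float]:
    """r = σ²_g / (σ²_g + σ²_gi/n_irg + σ²_ε/n_plot) and its delta-method SE.

    ``vc_cov`` is the 3×3 covariance of (σ²_g, σ²_gi, σ²_ε); without it
    the SE comes back NaN.
    """
    denom = sig_g + sig_gi / n_irg + sig_eps / n_plot
    if denom <= 0:
        return np.nan, np.nan
    r = sig_g / denom
    if vc_cov is None:
        return r, np.nan
    grad = np.array([
        (denom - sig_g) / denom**2,
        -sig_g / (n_irg * denom**2),
        -sig_g / (n_plot * denom**2),
    ])
    var = float(grad @ vc_cov @ grad)
    return r, np.sqrt(max(var, 0.0))


_ALL_RANDOM_TERMS = {
    "genotype": ("genotype",),
    "irg": ("treatment",),
    "genotype:irg": ("genotype", "treatment"),
    "rep": RANDOM_TERM_COLUMNS["rep"],
    "block": RANDOM_TERM_COLUMNS["block"],
    "column": RANDOM_TERM_COLUMNS["column"],
}


def repeatability(design: pd.DataFrame, y: np.ndarray | pd.Series) -> RepeatabilityEstimate:
    """Repeatability from the all-random reformulation of the trial model.

    Every design term (genotype, irg, genotype×irg, rep(irg),
    block(rep×irg), column(rep×irg)) is modeled as random around a fixed
    grand mean; σ²_g, σ²_gi and σ²_ε feed the repeatability formula with
    harmonic-mean replication numbers, and the SE comes from the
    delta method on the REML variance-component covariance.
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    y, design = y[mask], design.loc[mask]
    n = len(y)
    X = np.ones((n, 1))
    names = list(_ALL_RANDOM_TERMS)
    Zs = [_fixed_cellmean_matrix(design, cols)[0] for cols in _ALL_RANDOM_TERMS.values()]
    gamma, aux = _reml_optimize(y, X, Zs)
    sigma2_eps = aux["quad"] / (n - 1)
    vcs = {t: float(g * sigma2_eps) for t, g in zip(names, gamma)}
    vcs["residual"] = float(sigma2_eps)

    plots_per_geno = design.groupby("genotype").size().to_numpy()
    irgs_per_geno = design.groupby("genotype")["treatment"].nunique().to_numpy()
    n_plot = _harmonic_mean(plots_per_geno)
    n_irg = _harmonic_mean(irgs_per_geno)

    sig2 = np.array([vcs[t] for t in names] + [sigma2_eps])
    info = _vc_expected_information(sig2, X, Zs)
    full_cov = np.linalg.pinv(info)
    idx = [names.index("genotype"), names.index("genotype:irg"), len(names)]
    sub_cov = full_cov[np.ix_(idx, idx)]
    r, se = repeatability_from_components(
        vcs["genotype"], vcs["genotype:irg"], vcs["residual"], n_irg, n_plot, sub_cov
    )
    return RepeatabilityEstimate(r=r, se=se, n_irg=n_irg, n_plot=n_plot,
                                 variance_components=vcs)


# --------------------------------------------------------------------------
# Kenward–Roger fixed-effect F tests


def _marginal_contrasts(fit: MixedModelFit) -> dict[str, np.ndarray]:
    """Contrast matrices over cell means for genotype, irg, interaction."""
    cells = [c.split(":") for c in fit.cells]
    treatments = sorted({t for _, t in cells})
    pos = {tuple(c): i for i, c in enumerate(cells)}
    # marginal contrasts need every cell of a genotype; genotypes with an
    # empty cell (missingness or outlier removal) drop out of the tests
    genotypes = sorted({g for g, _ in cells
                        if all((g, t) in pos for t in treatments)})
    p = len(fit.cells)

    def cell_row(g, t):
        row = np.zeros(p)
        row[pos[(g, t)]] = 1.0
        return row

    def marg_g(g):
        return np.mean([cell_row(g, t) for t in treatments], axis=0)

    def marg_t(t):
        return np.mean([cell_row(g, t) for g in genotypes], axis=0)

    L = {}
    L["genotype"] = np.array([marg_g(g) - marg_g(genotypes[0]) for g in genotypes[1:]])
    L["irg"] = np.array([marg_t(t) - marg_t(treatments[0]) for t in treatments[1:]])
    inter = []
    for g in genotypes[1:]:
        for t in treatments[1:]:
            inter.append(cell_row(g, t) - cell_row(genotypes[0], t)
                         - cell_row(g, treatments[0]) + cell_row(genotypes[0], treatments[0]))
    L["genotype:irg"] = np.array(inter)
    return L


def _kenward_roger(fit: MixedModelFit, L: np.ndarray) -> tuple[float, float, float, float]:
    """Kenward–Roger scaled F statistic and denominator df for H0: Lβ = 0.

    Follows the standard small-sample algorithm: the Wald statistic is
    rescaled and referred to an F(q, m) distribution whose scale λ and
    denominator df m are chosen by matching the first two moments of the
    statistic, using the REML variance-component covariance.  On
    balanced designs this reproduces the classical ANOVA F and its
    stratum degrees of freedom exactly.
    """
    X, y = fit.X, fit.y
    n, p = X.shape
    terms = list(fit.spec.random_terms)
    sig2 = np.array([fit.variance_components[t] for t in terms]
                    + [fit.variance_components["residual"]])
    Zs = [fit.Z[t] for t in terms]
    Vds = [Z @ Z.T for Z in Zs] + [np.eye(n)]

    V = sum(s * Vd for s, Vd in zip(sig2, Vds))
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    Phi = np.linalg.inv(XtVinvX)
    beta = Phi @ X.T @ Vinv @ y

    info = _vc_expected_information(sig2, X, Zs)
    W = np.linalg.pinv(info)

    k = len(Vds)
    Pmats = [-(X.T @ Vinv @ Vd @ Vinv) @ X for Vd in Vds]

    q = L.shape[0]
    M = L.T @ np.linalg.inv(L @ Phi @ L.T) @ L  # Theta
    A1 = 0.0
    A2 = 0.0
    TP = [M @ Phi @ Pmats[i] @ Phi for i in range(k)]
    for i in range(k):
        for j in range(k):
            A1 += W[i, j] * np.trace(TP[i]) * np.trace(TP[j])
            A2 += W[i, j] * np.trace(TP[i] @ TP[j])
    B = (A1 + 6.0 * A2) / (2.0 * q)
    g = ((q + 1.0) * A1 - (q + 4.0) * A2) / ((q + 2.0) * A2) if A2 != 0 else 0.0
    c1 = g / (3.0 * q + 2.0 * (1.0 - g))
    c2 = (q - g) / (3.0 * q + 2.0 * (1.0 - g))
    c3 = (q + 2.0 - g) / (3.0 * q + 2.0 * (1.0 - g))
    V0 = 1.0 + c1 * B
    if abs(V0) < 1e-10:
        V0 = 0.0
    V1 = 1.0 - c2 * B
    V2 = 1.0 - c3 * B
    E_inv = 1.0 - A2 / q       # 1/E* with E* the expected-F correction
    ratio = E_inv / V1 if abs(V1) > 1e-12 else 1.0
    rho = (1.0 / q) * ratio**2 * V0 / V2 if abs(V2) > 1e-12 else np.inf
    m = 4.0 + (q + 2.0) / (q * rho - 1.0) if q * rho > 1.0 else np.inf
    if np.isfinite(m) and abs(m - 2.0) >= 0.01:
        lam = m * E_inv / (m - 2.0)
    else:
        lam = 1.0

    Lb = L @ beta
    # scaled *unadjusted* Wald statistic; Phi_A enters through the moments
    F_raw = float(Lb @ np.linalg.solve(L @ Phi @ L.T, Lb)) / q
    F = lam * F_raw
    pval = float(stats.f.sf(F, q, m)) if np.isfinite(m) else float(stats.chi2.sf(q * F, q))
    return F, float(q), float(m), pval


def fixed_effect_tests(fit: MixedModelFit) -> pd.DataFrame:
    """F tests (Kenward–Roger denominator df) for genotype, irg, interaction."""
    rows = []
    for term, L in _marginal_contrasts(fit).items():
        if L.size == 0:
            continue
        F, q, m, pval = _kenward_roger(fit, L)
        rows.append({"term": term, "F": F, "num_df": q, "den_df": m, "p": pval})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# per-trait pipeline


def preprocess_trait(design: pd.DataFrame, values: np.ndarray | pd.Series,
                     rescale: bool = True, outlier_alpha: float = 0.05,
                     lrt_alpha: float = 0.05) -> dict:
    """Run the full preprocessing chain for one trait and one year.

    Returns a dict with blues (genotype×treatment table on the original
    scale), the final fit, Box–Cox result, median, outlier mask, fixed
    effect tests, and the repeatability estimate.
    """
    y_raw = np.asarray(values, dtype=float)
    obs = np.isfinite(y_raw)
    design_obs = design.loc[obs]
    y_obs = y_raw[obs]

    if rescale:
        y_scaled, med = median_rescale(y_obs, "forward")
    else:
        y_scaled, med = y_obs, None
    bc = boxcox_select(y_scaled, design_obs)
    z = bc.forward(y_scaled) if bc.transformed else y_scaled

    full = fit_mixed_model(design_obs, z)
    flags = detect_outliers(full, alpha=outlier_alpha)
    design_clean = design_obs.loc[~flags]
    z_clean = z[~flags]

    final = backward_eliminate_random(design_clean, z_clean, alpha=lrt_alpha)
    blues = compute_blues(final, bc if bc.transformed else None, med)
    tests = fixed_effect_tests(final)
    rep = repeatability(design_clean, z_clean)
    return {
        "blues": blues, "fit": final, "boxcox": bc, "median": med,
        "outliers": flags, "outlier_index": list(design_obs.index[flags]),
        "fixed_tests": tests, "repeatability": rep,
    }


def preprocess_table(design: pd.DataFrame, traits: pd.DataFrame,
                     rescale: bool = True,
                     progress: Callable[[str], None] | None = None) -> dict:
    """Preprocess every trait column; collate BLUE / varcomp / r tables.

    The BLUE table is indexed by ``<genotype>_<treatment>`` sample ids
    (one row per genotype×treatment cell, e.g. 44 rows for the default
    trial) with one column per trait.
    """
    blues_cols, varcomp_rows, rep_rows, outlier_log = {}, [], [], {}
    for trait in traits.columns:
        if progress:
            progress(trait)
        res = preprocess_trait(design, traits[trait], rescale=rescale)
        tab = res["blues"]
        ids = tab["genotype"] + "_" + tab["treatment"]
        blues_cols[trait] = pd.Series(tab["blue"].to_numpy(), index=ids)
        vc = dict(res["fit"].variance_components)
        vc["trait"] = trait
        vc["lambda"] = res["boxcox"].lam
        varcomp_rows.append(vc)
        rep = res["repeatability"]
        rep_rows.append({"trait": trait, "r": rep.r, "se": rep.se,
                         "n_irg": rep.n_irg, "n_plot": rep.n_plot})
        outlier_log[trait] = res["outlier_index"]
    blues = pd.DataFrame(blues_cols)
    blues.index.name = "sample_id"
    return {
        "blues": blues,
        "varcomp": pd.DataFrame(varcomp_rows).set_index("trait"),
        "repeatability": pd.DataFrame(rep_rows).set_index("trait"),
        "outliers": outlier_log,
    }
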