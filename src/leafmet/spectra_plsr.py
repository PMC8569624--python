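"""Per-metabolite PLSR from 2151-band leaf spectra.

Each metabolite is regressed on the full reflectance spectrum with
partial least squares (PLS1, sequential covariance-maximizing component
extraction with X-deflation — the NIPALS scheme).  The workflow mirrors
a standard chemometric calibration:

* factor count A selected by leave-one-out cross-validation over
  A ∈ {0..12}, minimizing RMSECV (ties toward smaller A; A = 0 is the
  intercept-only model and marks the metabolite "not estimated");
* a "full dataset model" fit on all samples reports R² = 1 − RSS/TSS;
* "4-fold CV models": the samples are randomly split into four groups
  without replacement; each submodel selects its own A by LOO on its
  training 3/4 and predicts the held-out quarter;
  Q²_fold = 1 − PRESS/TSS with TSS about the training mean, so the
  mean predictor scores exactly 0.  A metabolite is "predicted" iff all
  four submodels use ≥ 1 factor with non-negative Q²;
* wavelength importance: per-model ordinal ranks of |β_PLS| (rank 1 =
  largest, ties broken by ascending wavelength), class mean ranks, and
  top-10% (215 wavelengths) selection-frequency histograms in 50-nm
  bins.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io_formats import WAVELENGTH_GRID
from .stress_metabolome import PCAResult, pca

__all__ = [
    "PLSRModel",
    "CVResult",
    "ImportanceResult",
    "plsr_fit",
    "select_factors_loo",
    "full_dataset_model",
    "fourfold_cv",
    "importance_analysis",
    "treatment_separation",
    "pca_on_predicted",
]


# --------------------------------------------------------------------------
# NIPALS core


def _nipals_path(X: np.ndarray, y: np.ndarray, A: int):
    """Extract up to A components; return (W, P, q, x_mean, y_mean, A_used).

    X and y are mean-centered internally.  Extraction stops early if the
    remaining X carries no covariance with y (numerical rank reached).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    if np.allclose(yc, 0):
        raise ValueError("zero-variance response")
    scale0 = float(np.linalg.norm(Xc)) * float(np.linalg.norm(yc)) + 1e-300

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    a_used = 0
    Xd = Xc.copy()
    for a in range(A):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale0:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            break
        P[:, a] = Xd.T @ t / tt
        q[a] = float(yc @ t) / tt
        W[:, a] = w
        Xd = Xd - np.outer(t, P[:, a])
        a_used += 1
    return W[:, :a_used], P[:, :a_used], q[:a_used], x_mean, y_mean, a_used


def _betas_along_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> list[np.ndarray]:
    """β_PLS for every truncation A = 1..A_used (nested NIPALS models)."""
    betas = []
    PtW = P.T @ W
    for a in range(1, W.shape[1] + 1):
        coef = np.linalg.solve(PtW[:a, :a], q[:a])
        betas.append(W[:, :a] @ coef)
    return betas


@dataclasses.dataclass
class PLSRModel:
    """A fitted PLS1 decomposition with its implied coefficient vector."""

    A: int
    weights: np.ndarray        # p × A
    x_loadings: np.ndarray     # p × A
    y_loadings: np.ndarray     # A
    beta: np.ndarray           # p (zero vector when A = 0)
    x_mean: np.ndarray
    y_mean: float
    r2: float = np.nan
    rmsecv: np.ndarray | None = None   # curve over A = 0..A_max

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.y_mean + (X - self.x_mean) @ self.beta

    def scores(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, dtype=float) - self.x_mean
        # scores via the direct projection R = W (P'W)^-1
        R = self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)
        return Xc @ R

    @property
    def estimated(self) -> bool:
        return self.A >= 1


def plsr_fit(X: np.ndarray, y: np.ndarray, A: int) -> PLSRModel:
    """Fit a PLS1 model with A factors (A = 0 is the mean-only model)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if A < 0:
        raise ValueError("A must be >= 0")
    if A > n - 1:
        raise ValueError(f"A={A} exceeds n-1={n - 1}")
    if A == 0:
        if np.allclose(y - y.mean(), 0):
            raise ValueError("zero-variance response")
        model = PLSRModel(A=0, weights=np.zeros((p, 0)), x_loadings=np.zeros((p, 0)),
                          y_loadings=np.zeros(0), beta=np.zeros(p),
                          x_mean=X.mean(axis=0), y_mean=float(y.mean()), r2=0.0)
        return model
    W, P, q, x_mean, y_mean, a_used = _nipals_path(X, y, A)
    if a_used < A:
        warnings.warn(f"requested {A} factors, numerical rank allowed {a_used}",
                      stacklevel=2)
    if a_used == 0:
        return plsr_fit(X, y, 0)
    beta = _betas_along_path(W, P, q)[-1]
    resid = y - (y_mean + (X - x_mean) @ beta)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss
    return PLSRModel(A=a_used, weights=W, x_loadings=P, y_loadings=q,
                     beta=beta, x_mean=x_mean, y_mean=y_mean, r2=r2)


def _path_predictions(X_train, y_train, X_new, A_max) -> np.ndarray:
    """Predictions of X_new for every A = 0..A_max from one training fit.

    Components beyond the numerical rank repeat the largest valid model.
    """
    W, P, q, x_mean, y_mean, a_used = _nipals_path(X_train, y_train, A_max)
    X_new = np.asarray(X_new, dtype=float)
    out = np.empty((X_new.shape[0], A_max + 1))
    out[:, 0] = y_mean
    if a_used:
        betas = _betas_along_path(W, P, q)
        Xc = X_new - x_mean
        for a in range(1, A_max + 1):
            beta = betas[min(a, a_used) - 1]
            out[:, a] = y_mean + Xc @ beta
    else:
        out[:, 1:] = y_mean
    return out


# --------------------------------------------------------------------------
# factor selection and models


def select_factors_loo(X: np.ndarray, y: np.ndarray,
                       A_max: int = 12) -> tuple[int, np.ndarray]:
    """RMSECV over A ∈ {0..A_max} by leave-one-out CV; A* = argmin.

    Ties break toward smaller A (parsimony).  A* = 0 means no latent
    variable beats the training-mean predictor.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for LOO factor selection")
    A_hi = min(A_max, n - 2)
    errors = np.empty((n, A_hi + 1))
    for i in range(n):
        keep = np.arange(n) != i
        preds = _path_predictions(X[keep], y[keep], X[i:i + 1], A_hi)
        errors[i] = preds[0] - y[i]
    rmsecv = np.sqrt(np.mean(errors**2, axis=0))
    if A_hi < A_max:
        rmsecv = np.concatenate([rmsecv, np.full(A_max - A_hi, rmsecv[-1])])
    a_star = int(np.argmin(rmsecv[: A_hi + 1]))
    return a_star, rmsecv


def full_dataset_model(X: np.ndarray, y: np.ndarray, A_max: int = 12) -> PLSRModel:
    """LOO-selected factor count, refit on all samples, with training R²."""
    a_star, rmsecv = select_factors_loo(X, y, A_max)
    model = plsr_fit(X, y, a_star)
    model.rmsecv = rmsecv
    return model


@dataclasses.dataclass
class CVResult:
    """4-fold cross-validated prediction of one metabolite."""

    fold_assignment: np.ndarray     # fold index per sample
    fold_A: list[int]
    fold_q2: list[float]
    q2_mean: float
    q2_pooled: float
    predicted: bool                 # all folds A ≥ 1 and Q² ≥ 0
    predictions: np.ndarray         # pooled held-out prediction per sample


def fourfold_cv(X: np.ndarray, y: np.ndarray, seed: int = 0, folds: int = 4,
                A_max: int = 12, q2_convention: str = "standard",
                stratify: np.ndarray | None = None,
                assignment: np.ndarray | None = None) -> CVResult:
    """Random k-fold (default 4) held-out prediction with per-fold Q².

    Folds are sampled without replacement (simple random split, or
    stratified when ``stratify`` labels are given); each fold's submodel
    selects its own factor count by LOO on its training samples, so no
    held-out information leaks into model selection.

    ``q2_convention='standard'`` computes Q² = 1 − PRESS/TSS (with TSS
    about the training mean); ``'printed'`` computes −PRESS/TSS, which is
    always ≤ 0 and kept only for comparison.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 2 * folds:
        raise ValueError(f"n={n} too small for {folds}-fold CV")
    if q2_convention not in ("standard", "printed"):
        raise ValueError(f"unknown q2_convention {q2_convention!r}")
    if assignment is not None:
        assignment = np.asarray(assignment, dtype=int)
        if assignment.shape != (n,):
            raise ValueError("explicit fold assignment must have one entry per sample")
        folds = int(assignment.max()) + 1
        return _cv_with_assignment(X, y, assignment, folds, A_max, q2_convention)
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratify is None:
        perm = rng.permutation(n)
        for f in range(folds):
            assignment[perm[f::folds]] = f
    else:
        strat = np.asarray(stratify)
        for label in np.unique(strat):
            idx = np.where(strat == label)[0]
            perm = rng.permutation(idx)
            for f in range(folds):
                assignment[perm[f::folds]] = f
    return _cv_with_assignment(X, y, assignment, folds, A_max, q2_convention)


def _cv_with_assignment(X, y, assignment, folds, A_max, q2_convention) -> CVResult:
    n = X.shape[0]
    fold_A, fold_q2 = [], []
    predictions = np.empty(n)
    for f in range(folds):
        val = assignment == f
        Xtr, ytr = X[~val], y[~val]
        a_star, _ = select_factors_loo(Xtr, ytr, A_max)
        model = plsr_fit(Xtr, ytr, a_star)
        yhat = model.predict(X[val])
        predictions[val] = yhat
        press = float(np.sum((y[val] - yhat) ** 2))
        tss = float(np.sum((y[val] - ytr.mean()) ** 2))
        if q2_convention == "standard":
            q2 = 1.0 - press / tss if tss > 0 else np.nan
        else:
            q2 = -press / tss if tss > 0 else np.nan
        fold_A.append(int(model.A))
        fold_q2.append(q2)

    press_all = float(np.sum((y - predictions) ** 2))
    # pooled TSS about the per-fold training means, accumulated per fold
    tss_all = 0.0
    for f in range(folds):
        val = assignment == f
        tss_all += float(np.sum((y[val] - y[~val].mean()) ** 2))
    q2_pooled = (1.0 - press_all / tss_all) if q2_convention == "standard" \
        else -press_all / tss_all
    predicted = all(a >= 1 for a in fold_A) and all(q >= 0 for q in fold_q2)
    return CVResult(
        fold_assignment=assignment, fold_A=fold_A, fold_q2=fold_q2,
        q2_mean=float(np.mean(fold_q2)), q2_pooled=q2_pooled,
        predicted=predicted, predictions=predictions,
    )


# --------------------------------------------------------------------------
# wavelength importance


@dataclasses.dataclass
class ImportanceResult:
    ranks: pd.DataFrame            # traits × wavelengths, 1 = most important
    top10: pd.DataFrame            # boolean, 215 True per trait
    class_mean_rank: pd.DataFrame  # classes × wavelengths
    histogram: pd.DataFrame        # per class and overall, counts per 50-nm bin
    top_k: int


def importance_analysis(betas: pd.DataFrame,
                        annotation: pd.DataFrame | None = None,
                        top_frac: float = 0.10,
                        bin_nm: int = 50) -> ImportanceResult:
    """Rank wavelengths by |β_PLS| per metabolite and tally the top 10%.

    ``betas`` is traits × 2151 (columns = the canonical wavelength grid).
    Ranks are ordinal (1..2151), ties broken by ascending wavelength.
    The top set is the ``floor(top_frac · 2151)`` lowest ranks (215 by
    default); the histogram counts (metabolite, wavelength) top-set
    memberships per ``bin_nm`` spectral bin, overall and per main class.
    """
    wl = np.asarray(betas.columns, dtype=int)
    if not np.array_equal(wl, WAVELENGTH_GRID):
        raise ValueError("beta columns must be the canonical 350..2500 grid")
    n_wl = wl.size
    top_k = int(np.floor(top_frac * n_wl))

    ranks = np.empty((len(betas), n_wl), dtype=int)
    for i, (_, row) in enumerate(betas.iterrows()):
        absb = np.abs(row.to_numpy(dtype=float))
        order = np.lexsort((wl, -absb))   # primary: |β| desc; tie: λ asc
        r = np.empty(n_wl, dtype=int)
        r[order] = np.arange(1, n_wl + 1)
        ranks[i] = r
    ranks_df = pd.DataFrame(ranks, index=betas.index, columns=wl)
    top10 = ranks_df <= top_k

    classes = {}
    if annotation is not None:
        ann = annotation.set_index("trait_id")
        for trait in betas.index:
            classes[trait] = ann.loc[trait, "main_class"] if trait in ann.index else "unknown"
    else:
        classes = {trait: "all" for trait in betas.index}
    class_series = pd.Series(classes)

    class_mean_rank = ranks_df.groupby(class_series).mean()

    edges = np.arange(350, 2501, bin_nm)
    hist_rows = []
    groups = {"overall": betas.index}
    for cls in class_mean_rank.index:
        groups[cls] = class_series.index[class_series == cls]
    for name, members in groups.items():
        member_top = top10.loc[members].to_numpy()
        selected_wl = np.repeat(wl[None, :], len(members), axis=0)[member_top]
        counts, _ = np.histogram(selected_wl, bins=edges)
        for left, cnt in zip(edges[:-1], counts):
            hist_rows.append({"group": name, "bin_left_nm": int(left),
                              "bin_right_nm": int(left + bin_nm), "count": int(cnt)})
    histogram = pd.DataFrame(hist_rows)
    return ImportanceResult(ranks=ranks_df, top10=top10,
                            class_mean_rank=class_mean_rank,
                            histogram=histogram, top_k=top_k)


# --------------------------------------------------------------------------
# discrimination PCA on predicted values


def treatment_separation(scores: pd.DataFrame, treatment: pd.Series,
                         n_pcs: int = 2) -> float:
    """Centroid distance over mean within-treatment spread in PC space."""
    S = scores.iloc[:, :n_pcs].to_numpy()
    labels = treatment.reindex(scores.index).to_numpy()
    cents, spreads = [], []
    for lab in pd.unique(labels):
        sub = S[labels == lab]
        c = sub.mean(axis=0)
        cents.append(c)
        spreads.append(np.sqrt(np.mean(np.sum((sub - c) ** 2, axis=1))))
    if len(cents) != 2:
        raise ValueError("treatment separation needs exactly two groups")
    return float(np.linalg.norm(cents[0] - cents[1]) / np.mean(spreads))


def pca_on_predicted(values: pd.DataFrame, q2: pd.Series, treatment: pd.Series,
                     q2_threshold: float = 0.5, log10: bool = True,
                     center: bool = True, scale: bool = True) -> dict:
    """PCA on the metabolites predicted with Q² above threshold.

    ``values`` are pooled held-out predictions (or observed values, for
    the comparison), samples × metabolites.  Returns the PCA plus the
    treatment-separation statistic on the first two PCs.
    """
    keep = [t for t in values.columns if q2.get(t, -np.inf) > q2_threshold]
    if len(keep) < 2:
        raise ValueError(
            f"only {len(keep)} metabolite(s) exceed Q² > {q2_threshold}; need >= 2"
        )
    result: PCAResult = pca(values[keep], log10=log10, center=center, scale=scale)
    sep = treatment_separation(result.scores, treatment)
    return {"pca": result, "separation": sep, "metabolites": keep}
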