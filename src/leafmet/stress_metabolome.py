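"""Stress-response statistics on BLUE tables.

Operates on the genotype×treatment BLUE tables produced by
:mod:`leafmet.trial_models`: k-nearest-neighbour imputation, PCA on
log10/centered/scaled intensities, cross-year median normalization,
hierarchical clustering (Pearson-correlation distance, complete
linkage), and the fold-change / Mann–Whitney / Benjamini–Hochberg
volcano classification with class-level summaries.

The volcano rule: a metabolite is a stress *decrease* when its
BH-adjusted two-sided Mann–Whitney p-value is below the FDR level and
the WL/WW mean fold change is < 0.5; an *increase* when adjusted p is
significant and FC > 2; otherwise *none*.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PCAResult",
    "impute_knn",
    "pca",
    "median_normalize_across_years",
    "hcluster",
    "fold_change",
    "mann_whitney_u",
    "bh_adjust",
    "volcano_classify",
    "volcano_table",
]


# --------------------------------------------------------------------------
# imputation


def impute_knn(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing cells with a distance-weighted k-NN average.

    Distances are Euclidean over the traits observed in both samples,
    computed on standardized values; neighbour weights use a Gaussian
    kernel exp(−d).  Observed cells are never changed.
    """
    X = table.to_numpy(dtype=float)
    n, m = X.shape
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the sample count {n}")
    if np.isnan(X).all(axis=0).any():
        bad = table.columns[np.isnan(X).all(axis=0)]
        raise ValueError(f"traits missing in all samples: {list(bad)[:5]}")
    if np.isnan(X).all(axis=1).any():
        raise ValueError("a sample has no observed values")
    if not np.isnan(X).any():
        return table.copy()

    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    sd[~np.isfinite(sd) | (sd == 0)] = 1.0
    Z = (X - mu) / sd
    obs = ~np.isnan(Z)

    out = X.copy()
    for i in range(n):
        miss_i = np.isnan(X[i])
        if not miss_i.any():
            continue
        dists = np.full(n, np.inf)
        for j in range(n):
            if j == i:
                continue
            both = obs[i] & obs[j]
            if not both.any():
                continue
            diff = Z[i, both] - Z[j, both]
            # scale up to the full trait count so distances are comparable
            dists[j] = np.sqrt(np.sum(diff**2) * m / both.sum())
        for t in np.where(miss_i)[0]:
            cand = np.where(obs[:, t] & np.isfinite(dists))[0]
            if cand.size == 0:
                raise ValueError(f"no donor for trait {table.columns[t]!r}")
            order = cand[np.argsort(dists[cand], kind="stable")][:k]
            w = np.exp(-dists[order])
            if w.sum() == 0:
                w = np.ones_like(w)
            out[i, t] = float(np.average(X[order, t], weights=w))
    return pd.DataFrame(out, index=table.index, columns=table.columns)


# --------------------------------------------------------------------------
# PCA


@dataclasses.dataclass
class PCAResult:
    scores: pd.DataFrame       # samples × PCs
    loadings: pd.DataFrame     # traits × PCs
    variance_fraction: np.ndarray
    processed: pd.DataFrame    # the matrix actually decomposed


def pca(table: pd.DataFrame, log10: bool = True, center: bool = True,
        scale: bool = True) -> PCAResult:
    """SVD-based PCA of a samples × traits table.

    With the default flags each value is log10-transformed, then each
    trait is centered (mean subtraction) and scaled (SD division).
    Nonpositive values under ``log10`` are floored at half the smallest
    positive value of that trait (counted and warned).  Zero-variance
    traits under ``scale`` are dropped with a warning.
    """
    X = table.to_numpy(dtype=float).copy()
    if np.isnan(X).any():
        raise ValueError("PCA input must be complete; impute first")
    if log10:
        n_floored = 0
        for j in range(X.shape[1]):
            nonpos = X[:, j] <= 0
            if nonpos.any():
                pos = X[~nonpos, j]
                if pos.size == 0:
                    raise ValueError(f"trait {table.columns[j]!r} has no positive values")
                X[nonpos, j] = 0.5 * pos.min()
                n_floored += int(nonpos.sum())
        if n_floored:
            warnings.warn(f"floored {n_floored} nonpositive values before log10",
                          stacklevel=2)
        X = np.log10(X)
    cols = np.asarray(table.columns)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping zero-variance traits: {cols[~keep][:5].tolist()}",
                          stacklevel=2)
            X, cols, sd = X[:, keep], cols[keep], sd[keep]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / sd

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    frac = s**2 / np.sum(s**2) if s.sum() > 0 else np.zeros_like(s)
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=table.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=cols, columns=pcs),
        variance_fraction=frac,
        processed=pd.DataFrame(X, index=table.index, columns=cols),
    )


# --------------------------------------------------------------------------
# cross-year normalization


def median_normalize_across_years(tables: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-year tables of the shared metabolites on one scale.

    Each value is multiplied by factor(trait, year) = median(trait across
    all years' samples) / median(trait within the year), which equalizes
    within-year medians to the combined median.  Only traits present in
    every year are kept; sample ids get a year prefix.
    """
    years = sorted(tables)
    common = set(tables[years[0]].columns)
    for yr in years[1:]:
        common &= set(tables[yr].columns)
    common = [c for c in tables[years[0]].columns if c in common]
    if not common:
        raise ValueError("no metabolites shared across years")

    stacked = pd.concat([tables[yr][common] for yr in years], axis=0)
    overall_med = stacked.median(axis=0)
    parts = []
    for yr in years:
        sub = tables[yr][common]
        year_med = sub.median(axis=0)
        if (year_med == 0).any():
            bad = year_med.index[year_med == 0]
            raise ValueError(f"zero within-year median for {list(bad)[:5]} in {yr}")
        factor = overall_med / year_med
        out = sub * factor
        out.index = [f"{yr}_{s}" for s in sub.index]
        parts.append(out)
    return pd.concat(parts, axis=0)


# --------------------------------------------------------------------------
# clustering


def hcluster(matrix: pd.DataFrame, axis: str = "rows") -> dict:
    """Agglomerative clustering with 1 − Pearson r distance, complete linkage.

    ``axis='rows'`` clusters the rows (samples); ``'cols'`` the columns.
    Returns the merge tree: scipy linkage matrix plus leaf labels and the
    condensed distance vector.  Constant rows have undefined correlation
    and raise.
    """
    data = matrix.to_numpy(dtype=float)
    labels = list(matrix.index)
    if axis == "cols":
        data, labels = data.T, list(matrix.columns)
    if data.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    sd = data.std(axis=1)
    if (sd == 0).any():
        bad = [labels[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"constant rows have undefined correlation: {bad[:5]}")
    corr = np.corrcoef(data)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    Z = linkage(condensed, method="complete")
    return {"linkage": Z, "labels": labels, "distances": condensed}


# --------------------------------------------------------------------------
# volcano statistics


def fold_change(table: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """WL/WW ratio of group means per trait, on non-log-transformed values."""
    g = groups.reindex(table.index)
    wl = table.loc[g == "WL"]
    ww = table.loc[g == "WW"]
    if wl.empty or ww.empty:
        raise ValueError("both WL and WW groups must be non-empty")
    mean_wl = wl.mean(axis=0)
    mean_ww = ww.mean(axis=0)
    fc = mean_wl / mean_ww
    zero = mean_ww == 0
    if zero.any():
        warnings.warn(f"zero WW mean for {list(fc.index[zero])[:5]}; FC set missing",
                      stacklevel=2)
        fc[zero] = np.nan
    return fc.rename("FC")


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with midrank ties.

    Exact p by enumeration of all group assignments when n_x + n_y ≤ 12
    and there are no ties; otherwise the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def volcano_table(table: pd.DataFrame, groups: pd.Series,
                  fc_lo: float = 0.5, fc_hi: float = 2.0,
                  fdr: float = 0.05) -> pd.DataFrame:
    """Fold change, Mann–Whitney p, BH-adjusted p and category per trait."""
    g = groups.reindex(table.index)
    fc = fold_change(table, groups)
    pvals = []
    for trait in table.columns:
        col = table[trait]
        x = col[g == "WL"].dropna().to_numpy()
        y = col[g == "WW"].dropna().to_numpy()
        pvals.append(mann_whitney_u(x, y)[1])
    p = np.asarray(pvals)
    p_adj = bh_adjust(p)
    cat = np.where(
        (p_adj < fdr) & (fc < fc_lo), "decrease",
        np.where((p_adj < fdr) & (fc > fc_hi), "increase", "none"),
    )
    return pd.DataFrame({
        "trait_id": table.columns, "FC": fc.to_numpy(), "p": p,
        "p_adj": p_adj, "category": cat,
    }).set_index("trait_id")


def volcano_classify(records: pd.DataFrame,
                     annotation: pd.DataFrame | None = None) -> dict:
    """Summarize a volcano table: category rates, mean±SD FC, class counts.

    ``records`` is the output of :func:`volcano_table`.  Percentages are
    of FDR-significant metabolites falling in the decrease / increase
    category, over all tested metabolites; the mean FC ± SD is reported
    within each category.  With an annotation table (trait_id,
    main_class, subclass) per-class and per-subclass counts are added.
    """
    n = len(records)
    out: dict = {"records": records, "n_metabolites": n}
    for cat in ("decrease", "increase"):
        sub = records[records["category"] == cat]
        out[f"n_{cat}"] = len(sub)
        out[f"pct_{cat}"] = 100.0 * len(sub) / n if n else np.nan
        out[f"mean_fc_{cat}"] = float(sub["FC"].mean()) if len(sub) else np.nan
        out[f"sd_fc_{cat}"] = float(sub["FC"].std(ddof=1)) if len(sub) > 1 else np.nan
    out["pct_regulated"] = out["pct_decrease"] + out["pct_increase"]
    if annotation is not None:
        ann = annotation.set_index("trait_id")
        rows = []
        for cat in ("decrease", "increase"):
            ids = records.index[records["category"] == cat]
            known = [i for i in ids if i in ann.index]
            sub = ann.loc[known]
            for (mc, sc), grp in sub.groupby(["main_class", "subclass"]):
                rows.append({"category": cat, "main_class": mc,
                             "subclass": sc, "n": len(grp)})
        out["class_summary"] = pd.DataFrame(
            rows, columns=["category", "main_class", "subclass", "n"]
        )
    return out
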