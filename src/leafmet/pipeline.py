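"""End-to-end orchestration: simulate → preprocess → stress-stats →
indices → plsr → report.

Years are analyzed individually (separate designs, separate BLUE tables,
separate volcano and PLSR analyses); only the hierarchical clustering of
the metabolites shared across years combines them, after cross-year
median normalization.

Per year the stages are:

1. *simulate* (synthetic mode) — trial design, plot metabolite
   intensities, and five leaf spectra per plot from
   :mod:`leafmet.synthetic_data`;
2. *preprocess* — full mixed-model BLUEs for every metabolite
   (median-rescaled) and vegetation index (raw scale); plot spectra are
   averaged from leaves, and the spectral predictor matrix for PLSR is
   the genotype×treatment cell mean of the plot spectra per band;
3. *stress-stats* — imputation, volcano classification, and PCA of the
   treatment-significant metabolites;
4. *indices* — vegetation indices at plot level, preprocessed to BLUEs,
   summarized as treatment means ± SD with a Mann–Whitney test;
5. *plsr* — per-metabolite full-dataset estimation and 4-fold CV
   prediction for the treatment-significant metabolites, wavelength
   importance, and the observed-vs-predicted discrimination PCA.

Every run records a manifest (config hash, seeds, per-stage row counts)
and is byte-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (RunConfig, SpectraTable, average_replicate_spectra,
                         config_hash, get_logger, write_spectra, write_traits)
from .synthetic_data import (SimConfig, generate_annotation, generate_metabolome,
                             generate_spectra, generate_trial, leaf_to_plot)
from .trial_models import preprocess_table
from .stress_metabolome import (impute_knn, median_normalize_across_years,
                                hcluster, mann_whitney_u, pca, volcano_classify,
                                volcano_table)
from .veg_indices import compute_vis
from .spectra_plsr import (fourfold_cv, full_dataset_model, importance_analysis,
                           pca_on_predicted, treatment_separation)

__all__ = ["PipelineError", "RunManifest", "run_year", "run_all"]

VI_TRAITS = ("NDVI", "sPRI", "CRI", "WI", "WI_over_NDVI")


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and offending item."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    stage_counts: dict[str, dict]
    version: str
    started: str
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _year_seed(base_seed: int, year: int) -> int:
    return int((base_seed * 10007 + year) % (2**31 - 1))


def _treatment_labels(sample_ids) -> pd.Series:
    return pd.Series([s.rsplit("_", 1)[1] for s in sample_ids], index=sample_ids,
                     name="treatment")


def _cellmean_spectra(plot_spectra: SpectraTable, design: pd.DataFrame) -> pd.DataFrame:
    """Genotype×treatment mean spectrum per band, indexed like the BLUE tables."""
    cells = design["genotype"] + "_" + design["treatment"]
    means = plot_spectra.data.groupby(cells.reindex(plot_spectra.data.index)).mean()
    return means.sort_index()


def run_year(config: RunConfig, year: int, sim_config: SimConfig | None = None,
             inputs: dict | None = None, logger=None) -> dict:
    """Run the full single-year analysis.

    Without ``inputs`` a synthetic trial is simulated.  With ``inputs``
    (a dict of file paths: design, metabolites, spectra, and optionally
    annotation) the user-supplied tables are analyzed instead; leaf-level
    spectra (``<plot>_L<k>`` sample ids) are averaged to plot level.
    """
    log = logger or get_logger()
    if config.folds != 4:
        log.info("non-default fold count %d (the standard analysis uses 4)",
                 config.folds)
    seed = _year_seed(config.seed, year)
    counts: dict[str, dict] = {}

    if inputs is None:
        sim = dataclasses.replace(sim_config or SimConfig(), seed=seed)
        design, truth = generate_trial(sim)
        metabolites = generate_metabolome(design, truth, sim)
        leaf_spectra = generate_spectra(design, truth, sim)
        annotation = generate_annotation(sim)
        counts["simulate"] = {"plots": len(design),
                              "metabolites": metabolites.shape[1],
                              "leaf_spectra": leaf_spectra.n_samples}
        log.info("year %d simulate: %d plots, %d metabolites, %d leaf spectra",
                 year, len(design), metabolites.shape[1], leaf_spectra.n_samples)
    else:
        from .io_formats import read_annotation, read_spectra, read_traits
        for key, stage in (("design", "preprocess"), ("metabolites", "preprocess"),
                           ("spectra", "indices")):
            path = inputs.get(key)
            if path is None or not Path(path).exists():
                raise PipelineError(stage, f"missing {key} input: {path}")
        design = pd.read_csv(inputs["design"], index_col=0)
        metabolites = read_traits(inputs["metabolites"])
        leaf_spectra = read_spectra(inputs["spectra"])
        annotation = (read_annotation(inputs["annotation"])
                      if inputs.get("annotation") else None)
        truth = None

    # --- preprocess
    if any("_L" in s for s in leaf_spectra.sample_ids):
        plot_spectra = average_replicate_spectra(leaf_spectra,
                                                 leaf_to_plot(leaf_spectra))
    else:
        plot_spectra = leaf_spectra
    try:
        pre = preprocess_table(design, metabolites, rescale=True)
    except Exception as exc:  # pragma: no cover - surfaced with stage context
        raise PipelineError("preprocess", str(exc)) from exc
    blues_met = pre["blues"]
    blues_spectra = _cellmean_spectra(plot_spectra, design)
    counts["preprocess"] = {"blue_samples": len(blues_met),
                            "traits": blues_met.shape[1]}
    log.info("year %d preprocess: %d BLUE samples x %d traits",
             year, *blues_met.shape)

    # --- stress statistics
    k = min(config.knn_k, len(blues_met) - 1)
    imputed = impute_knn(blues_met, k=k) if blues_met.isna().any().any() else blues_met
    treatment = _treatment_labels(imputed.index)
    volcano = volcano_table(imputed, treatment, fc_lo=config.fc_lo,
                            fc_hi=config.fc_hi, fdr=config.fdr)
    summary = volcano_classify(volcano, annotation)
    significant = list(volcano.index[volcano["p"] < 0.05])
    if len(significant) >= 2:
        pca_obs = pca(imputed[significant])
    else:
        pca_obs = None
    counts["stress_stats"] = {"significant": len(significant),
                              "increase": summary["n_increase"],
                              "decrease": summary["n_decrease"]}
    log.info("year %d stress-stats: %d significant, %d increase, %d decrease",
             year, len(significant), summary["n_increase"], summary["n_decrease"])

    # --- vegetation indices
    vis_plot = compute_vis(plot_spectra)
    vi_pre = preprocess_table(design, vis_plot[list(VI_TRAITS)], rescale=False)
    vi_blues = vi_pre["blues"]
    vi_treatment = _treatment_labels(vi_blues.index)
    vi_rows = []
    for vi in VI_TRAITS:
        ww = vi_blues.loc[vi_treatment == "WW", vi].dropna()
        wl = vi_blues.loc[vi_treatment == "WL", vi].dropna()
        _, p = mann_whitney_u(wl.to_numpy(), ww.to_numpy())
        vi_rows.append({"index": vi, "mean_WW": ww.mean(), "sd_WW": ww.std(ddof=1),
                        "mean_WL": wl.mean(), "sd_WL": wl.std(ddof=1), "p": p})
    vi_summary = pd.DataFrame(vi_rows).set_index("index")
    counts["indices"] = {"plots": len(vis_plot), "indices": len(VI_TRAITS)}

    # --- PLSR
    X = blues_spectra.loc[imputed.index].to_numpy()
    models, cvs = {}, {}
    for trait in significant:
        y = imputed[trait].to_numpy(dtype=float)
        models[trait] = full_dataset_model(X, y, A_max=config.max_factors)
        cvs[trait] = fourfold_cv(X, y, seed=seed, folds=config.folds,
                                 A_max=config.max_factors)
    model_summary = pd.DataFrame({
        "A": {t: m.A for t, m in models.items()},
        "R2": {t: m.r2 for t, m in models.items()},
        "estimated": {t: m.estimated for t, m in models.items()},
        "Q2_mean": {t: c.q2_mean for t, c in cvs.items()},
        "Q2_pooled": {t: c.q2_pooled for t, c in cvs.items()},
        "predicted": {t: c.predicted for t, c in cvs.items()},
    })
    model_summary.index.name = "trait_id"

    est = model_summary[model_summary["estimated"]]
    prd = model_summary[model_summary["predicted"]]
    plsr_stats = {
        "n_models": len(model_summary),
        "n_estimated": int(model_summary["estimated"].sum()),
        "pct_estimated": 100.0 * model_summary["estimated"].mean() if len(model_summary) else np.nan,
        "mean_r2_estimated": float(est["R2"].mean()) if len(est) else np.nan,
        "n_predicted": int(model_summary["predicted"].sum()),
        "pct_predicted": 100.0 * model_summary["predicted"].mean() if len(model_summary) else np.nan,
        "mean_q2_predicted": float(prd["Q2_mean"].mean()) if len(prd) else np.nan,
    }
    counts["plsr"] = {"models": len(model_summary),
                      "estimated": plsr_stats["n_estimated"],
                      "predicted": plsr_stats["n_predicted"]}
    log.info("year %d plsr: %d models, %d estimated, %d predicted",
             year, *counts["plsr"].values())

    betas = pd.DataFrame(
        {t: m.beta for t, m in models.items() if m.estimated}
    ).T
    importance = None
    if len(betas):
        betas.columns = blues_spectra.columns
        importance = importance_analysis(betas, annotation)

    q2 = model_summary["Q2_mean"]
    accurate = q2[q2 > config.q2_accurate]
    discrimination = None
    if len(accurate) >= 2:
        predicted_vals = pd.DataFrame(
            {t: cvs[t].predictions for t in accurate.index}, index=imputed.index
        )
        disc_pred = pca_on_predicted(predicted_vals, q2, treatment,
                                     q2_threshold=config.q2_accurate)
        obs_pca = pca(imputed[list(accurate.index)])
        sep_obs = treatment_separation(obs_pca.scores, treatment)
        discrimination = {
            "separation_observed": sep_obs,
            "separation_predicted": disc_pred["separation"],
            "ratio": disc_pred["separation"] / sep_obs if sep_obs else np.nan,
            "pca_predicted": disc_pred["pca"],
            "pca_observed": obs_pca,
        }

    return {
        "year": year, "seed": seed, "design": design, "truth": truth,
        "metabolites": metabolites, "leaf_spectra": leaf_spectra,
        "plot_spectra": plot_spectra, "annotation": annotation,
        "blues_metabolites": blues_met, "imputed": imputed,
        "blues_spectra": blues_spectra, "varcomp": pre["varcomp"],
        "repeatability": pre["repeatability"], "treatment": treatment,
        "volcano": volcano, "volcano_summary": summary,
        "significant": significant, "pca_observed": pca_obs,
        "vi_blues": vi_blues, "vi_summary": vi_summary,
        "models": models, "cv": cvs, "model_summary": model_summary,
        "plsr_stats": plsr_stats, "importance": importance,
        "discrimination": discrimination, "stage_counts": counts,
    }


def run_all(config: RunConfig | None = None, outdir: str | Path | None = None,
            sim_config: SimConfig | None = None,
            inputs: dict | None = None, logger=None) -> dict:
    """Run every year of the study and collate the report.

    Synthetic mode by default; pass ``inputs`` (year → dict of file
    paths) to analyze user-supplied tables.  With ``outdir`` set, stage
    outputs are written as CSV/JSON so any stage can be re-entered
    independently.
    """
    config = config or RunConfig()
    log = logger or get_logger()
    started = datetime.datetime.now().isoformat(timespec="seconds")
    log.info("run-all: seed=%d config=%s", config.seed, config_hash(config))

    years = {}
    for year in config.years:
        years[year] = run_year(config, year, sim_config=sim_config,
                               inputs=None if inputs is None else inputs.get(year),
                               logger=log)

    # cross-year clustering of shared significant metabolites
    clustering = None
    sig_sets = [set(res["significant"]) for res in years.values()]
    shared = sorted(set.intersection(*sig_sets)) if sig_sets else []
    if len(shared) >= 2 and len(years) >= 2:
        tables = {yr: res["imputed"][shared] for yr, res in years.items()}
        combined = median_normalize_across_years(tables)
        processed = pca(combined, log10=True, center=True, scale=True).processed
        clustering = {
            "combined": combined,
            "samples": hcluster(processed, axis="rows"),
            "metabolites": hcluster(processed, axis="cols"),
            "shared_metabolites": shared,
        }

    report = {
        "volcano": {yr: {k: res["volcano_summary"][k]
                         for k in ("pct_decrease", "pct_increase", "pct_regulated",
                                   "mean_fc_increase", "sd_fc_increase",
                                   "mean_fc_decrease", "sd_fc_decrease")}
                    for yr, res in years.items()},
        "vegetation_indices": {yr: res["vi_summary"].to_dict(orient="index")
                               for yr, res in years.items()},
        "plsr": {yr: res["plsr_stats"] for yr, res in years.items()},
    }

    manifest = RunManifest(
        config_hash=config_hash(config),
        seeds={str(yr): res["seed"] for yr, res in years.items()},
        stage_counts={str(yr): res["stage_counts"] for yr, res in years.items()},
        version=__version__,
        started=started,
        finished=datetime.datetime.now().isoformat(timespec="seconds"),
    )
    result = {"years": years, "clustering": clustering, "report": report,
              "manifest": manifest, "config": config}
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for yr, res in result["years"].items():
        d = outdir / str(yr)
        d.mkdir(exist_ok=True)
        res["design"].to_csv(d / "design.csv")
        write_traits(res["metabolites"], d / "metabolites.csv")
        write_spectra(res["plot_spectra"], d / "plot_spectra.csv")
        write_traits(res["blues_metabolites"], d / "blues_metabolites.csv")
        write_traits(res["blues_spectra"], d / "blues_spectra.csv")
        res["varcomp"].to_csv(d / "varcomp.csv")
        res["repeatability"].to_csv(d / "repeatability.csv")
        res["volcano"].to_csv(d / "volcano.csv")
        res["vi_blues"].to_csv(d / "vi_blues.csv")
        res["vi_summary"].to_csv(d / "vi_summary.csv")
        res["model_summary"].to_csv(d / "plsr_summary.csv")
        res["annotation"].to_csv(d / "annotation.csv", index=False)
        if res["importance"] is not None:
            res["importance"].histogram.to_csv(d / "top10_frequency.csv", index=False)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    (outdir / "report.json").write_text(
        json.dumps(result["report"], indent=2, sort_keys=True, default=_default))
    (outdir / "manifest.json").write_text(result["manifest"].to_json())
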