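import numpy as np
import pandas as pd
import pytest

import leafmet as lm
from leafmet.trial_models import (BOXCOX_GRID, MixedModelSpec, boxcox_select,
                                  fit_mixed_model, fixed_effect_tests,
                                  lrt_random_term, median_rescale,
                                  repeatability_from_components)

from conftest import balanced_design


def simulate_split_plot(design, rep_sd, resid_sd, seed, genotype_sd=1.0,
                        treatment_shift=1.0):
    """Genotype shifts + rep(irg) random effects + iid residual."""
    rng = np.random.default_rng(seed)
    genos = sorted(design["genotype"].unique())
    g_eff = {g: rng.normal(0, genotype_sd) for g in genos}
    reps = design["treatment"] + ":" + design["rep"]
    r_eff = {r: rng.normal(0, rep_sd) for r in reps.unique()}
    y = np.array([
        g_eff[row.genotype] + (treatment_shift if row.treatment == "WL" else 0.0)
        + r_eff[row.treatment + ":" + row.rep] + rng.normal(0, resid_sd)
        for row in design.itertuples()
    ])
    return y


def classical_anova(design, y):
    """Method-of-moments variance components and F tests for the balanced
    genotype x treatment x rep design with random rep(irg)."""
    df = design.copy()
    df["y"] = y
    df["cell"] = df.genotype + ":" + df.treatment
    df["repid"] = df.treatment + ":" + df.rep
    G = df.genotype.nunique()
    T = df.treatment.nunique()
    K = df.rep.nunique()
    gm = df.y.mean()
    ss = {}
    ss["cell"] = sum(len(s) * (s.y.mean() - gm) ** 2 for _, s in df.groupby("cell"))
    ss["rep"] = sum(len(s) * (s.y.mean() - df[df.treatment == s.treatment.iloc[0]].y.mean()) ** 2
                    for _, s in df.groupby("repid"))
    ss["gen"] = sum(len(s) * (s.y.mean() - gm) ** 2 for _, s in df.groupby("genotype"))
    ss["trt"] = sum(len(s) * (s.y.mean() - gm) ** 2 for _, s in df.groupby("treatment"))
    ss["tot"] = ((df.y - gm) ** 2).sum()
    ss["int"] = ss["cell"] - ss["gen"] - ss["trt"]
    ss["res"] = ss["tot"] - ss["cell"] - ss["rep"]
    dfs = {"rep": T * (K - 1), "gen": G - 1, "trt": T - 1,
           "int": (G - 1) * (T - 1)}
    dfs["res"] = len(df) - G * T - dfs["rep"]
    ms = {k: ss[k] / dfs[k] for k in dfs}
    return {
        "var_rep": (ms["rep"] - ms["res"]) / G,
        "var_res": ms["res"],
        "F_gen": ms["gen"] / ms["res"], "df_gen": (dfs["gen"], dfs["res"]),
        "F_trt": ms["trt"] / ms["rep"], "df_trt": (dfs["trt"], dfs["rep"]),
        "F_int": ms["int"] / ms["res"], "df_int": (dfs["int"], dfs["res"]),
    }


class TestMedianRescale:
    def test_forward_divides_by_median(self):
        scaled, med = median_rescale([2.0, 4.0, 6.0])
        assert med == 4.0
        np.testing.assert_allclose(scaled, [0.5, 1.0, 1.5])

    def test_back_inverts_forward(self, rng):
        v = rng.gamma(3.0, 2.0, size=30)
        scaled, med = median_rescale(v)
        back, _ = median_rescale(scaled, "back", med)
        np.testing.assert_allclose(back, v)

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError, match="median"):
            median_rescale([-1.0, 0.0, 1.0])


class TestBoxCox:
    def test_grid_is_nine_half_steps(self):
        np.testing.assert_allclose(BOXCOX_GRID, np.arange(-2, 2.5, 0.5))

    def test_log_transform_of_e_is_one(self):
        bc = lm.BoxCoxResult(lam=0.0, transformed=True, profile_loglik={})
        np.testing.assert_allclose(bc.forward(np.array([np.e])), [1.0])

    @pytest.mark.parametrize("lam", [-2.0, -0.5, 0.0, 0.5, 2.0])
    def test_inverse_undoes_forward(self, lam, rng):
        bc = lm.BoxCoxResult(lam=lam, transformed=True, profile_loglik={})
        y = rng.gamma(5.0, 1.0, size=40) + 0.1
        np.testing.assert_allclose(bc.inverse(bc.forward(y)), y, rtol=1e-10)

    def test_identity_scale_data_selects_lambda_one(self, small_balanced_design):
        # spread must be large relative to the mean, otherwise the profile
        # log-likelihood is nearly flat in lambda
        y = 10.0 + simulate_split_plot(small_balanced_design, 0.0, 1.5, seed=2,
                                       genotype_sd=3.0, treatment_shift=3.0)
        assert (y > 0).all()
        bc = boxcox_select(y, small_balanced_design)
        assert bc.lam == 1.0 and not bc.transformed

    def test_lognormal_data_selects_log(self, small_balanced_design):
        z = simulate_split_plot(small_balanced_design, 0.0, 0.4, seed=5,
                                genotype_sd=1.0, treatment_shift=1.0)
        bc = boxcox_select(np.exp(z), small_balanced_design)
        assert bc.lam == 0.0

    def test_nonpositive_values_instruct_shift(self, small_balanced_design):
        y = np.linspace(-1, 1, len(small_balanced_design))
        with pytest.raises(ValueError, match="shift"):
            boxcox_select(y, small_balanced_design)


class TestREML:
    def test_balanced_noiseless_blues_equal_cell_means(self):
        design = balanced_design(4, 3)
        y = simulate_split_plot(design, 0.0, 1.0, seed=1)
        fit = fit_mixed_model(design, y)
        cells = design.genotype + ":" + design.treatment
        cell_means = pd.Series(y, index=design.index).groupby(cells).mean()
        est = fit.cell_estimates()
        np.testing.assert_allclose(est[cell_means.index], cell_means, atol=1e-8)

    def test_pure_genotype_shift_moves_blue_by_delta(self):
        design = balanced_design(4, 2)
        y = np.ones(len(design))
        delta = 3.25
        y[(design.genotype == "G02").to_numpy()] += delta
        fit = fit_mixed_model(design, y, MixedModelSpec(()))
        est = fit.cell_estimates()
        np.testing.assert_allclose(est["G02:WW"] - est["G01:WW"], delta, atol=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_reml_matches_anova_method_of_moments(self, seed):
        design = balanced_design(6, 3)
        y = simulate_split_plot(design, rep_sd=0.7, resid_sd=1.0, seed=seed)
        oracle = classical_anova(design, y)
        if oracle["var_rep"] <= 0:
            pytest.skip("MoM estimate at boundary; REML truncates")
        fit = fit_mixed_model(design, y, MixedModelSpec(("rep",)))
        np.testing.assert_allclose(fit.variance_components["rep"],
                                   oracle["var_rep"], atol=1e-6)
        np.testing.assert_allclose(fit.variance_components["residual"],
                                   oracle["var_res"], atol=1e-6)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_kenward_roger_equals_classical_f_on_balanced_design(self, seed):
        design = balanced_design(6, 3)
        y = simulate_split_plot(design, rep_sd=0.7, resid_sd=1.0, seed=seed)
        oracle = classical_anova(design, y)
        if oracle["var_rep"] <= 0:
            pytest.skip("boundary")
        fit = fit_mixed_model(design, y, MixedModelSpec(("rep",)))
        tests = fixed_effect_tests(fit).set_index("term")
        for term, fkey, dkey in (("genotype", "F_gen", "df_gen"),
                                 ("irg", "F_trt", "df_trt"),
                                 ("genotype:irg", "F_int", "df_int")):
            np.testing.assert_allclose(tests.loc[term, "F"], oracle[fkey], rtol=1e-4)
            np.testing.assert_allclose(tests.loc[term, "den_df"],
                                       oracle[dkey][1], rtol=1e-3)

    def test_saturated_design_warns(self):
        # one observation per cell: residual variance not estimable
        design = balanced_design(2, 1)
        with pytest.warns(UserWarning, match="saturated"):
            fit = fit_mixed_model(design, np.arange(4.0), MixedModelSpec(()))
        assert fit.variance_components["residual"] == 0.0


class TestOutliers:
    def test_gross_outlier_flagged(self):
        design = balanced_design(6, 3)
        y = simulate_split_plot(design, 0.3, 0.5, seed=9)
        y[7] += 10 * 0.5
        fit = fit_mixed_model(design, y)
        flags = lm.detect_outliers(fit)
        assert flags[7]
        assert flags.sum() <= 2

    def test_clean_data_rarely_flagged(self):
        design = balanced_design(6, 3)
        clean = 0
        n_seeds = 40
        for seed in range(n_seeds):
            y = simulate_split_plot(design, 0.3, 0.5, seed=100 + seed)
            fit = fit_mixed_model(design, y, MixedModelSpec(("rep",)))
            clean += int(lm.detect_outliers(fit).sum() == 0)
        assert clean / n_seeds >= 0.85

    def test_single_observation_warns(self):
        design = balanced_design(1, 1, treatments=("WW",))
        with pytest.warns(UserWarning, match="saturated"):
            fit = fit_mixed_model(design, np.array([1.0]), MixedModelSpec(()))
        with pytest.warns(UserWarning, match="too few"):
            flags = lm.detect_outliers(fit)
        assert not flags.any()


class TestBackwardElimination:
    def test_zero_variance_terms_eliminated(self):
        design = balanced_design(8, 3)
        removed = 0
        for seed in range(6):
            y = simulate_split_plot(design, rep_sd=0.0, resid_sd=0.5, seed=seed)
            fit = lm.backward_eliminate_random(design, y, MixedModelSpec(("rep",)))
            removed += int(fit.spec.random_terms == ())
        assert removed >= 5

    def test_large_variance_term_retained(self):
        design = balanced_design(8, 3)
        y = simulate_split_plot(design, rep_sd=3.0, resid_sd=0.3, seed=2)
        fit = lm.backward_eliminate_random(design, y, MixedModelSpec(("rep",)))
        assert "rep" in fit.spec.random_terms

    def test_no_random_terms_returned_unchanged(self):
        design = balanced_design(4, 2)
        y = simulate_split_plot(design, 0.0, 1.0, seed=3)
        fit = lm.backward_eliminate_random(design, y, MixedModelSpec(()))
        assert fit.spec.random_terms == ()

    def test_lrt_boundary_mixture_halves_p(self):
        design = balanced_design(6, 3)
        y = simulate_split_plot(design, rep_sd=1.0, resid_sd=0.5, seed=4)
        full = fit_mixed_model(design, y, MixedModelSpec(("rep",)))
        red = fit_mixed_model(design, y, MixedModelSpec(()))
        p_mix = lrt_random_term(full, red, boundary_mixture=True)
        p_plain = lrt_random_term(full, red, boundary_mixture=False)
        np.testing.assert_allclose(p_plain, 2 * p_mix)


class TestBlues:
    def test_full_panel_yields_44_rows(self):
        design, truth = lm.generate_trial(lm.SimConfig(seed=6, n_metabolites=2))
        mets = lm.generate_metabolome(design, truth, lm.SimConfig(seed=6, n_metabolites=2))
        res = lm.preprocess_trait(design, mets["met001"])
        assert len(res["blues"]) == 44

    def test_log_lambda_back_transform_is_exp(self):
        design = balanced_design(3, 2)
        z = simulate_split_plot(design, 0.0, 0.0, seed=1, genotype_sd=0.5)
        fit = fit_mixed_model(design, z, MixedModelSpec(()))
        bc = lm.BoxCoxResult(lam=0.0, transformed=True, profile_loglik={})
        blues = lm.compute_blues(fit, bc)
        raw = fit.cell_estimates()
        row = blues.set_index(blues.genotype + ":" + blues.treatment)["blue"]
        np.testing.assert_allclose(row[raw.index], np.exp(raw), rtol=1e-10)

    def test_median_back_multiplication(self):
        design = balanced_design(3, 2)
        y = np.full(len(design), 2.0)
        fit = fit_mixed_model(design, y, MixedModelSpec(()))
        blues = lm.compute_blues(fit, None, median=5.0)
        np.testing.assert_allclose(blues["blue"], 10.0)


class TestRepeatability:
    def test_hand_computed_value(self):
        r, se = repeatability_from_components(2.0, 1.0, 1.0, n_irg=2, n_plot=4)
        np.testing.assert_allclose(r, 2.0 / 2.75)
        np.testing.assert_allclose(r, 0.72727, atol=5e-6)
        assert np.isnan(se)

    def test_degenerate_limits(self):
        r0, _ = repeatability_from_components(0.0, 1.0, 1.0, 2, 4)
        r1, _ = repeatability_from_components(2.0, 0.0, 0.0, 2, 4)
        assert r0 == 0.0 and r1 == 1.0

    def test_all_zero_returns_missing(self):
        r, se = repeatability_from_components(0.0, 0.0, 0.0, 2, 4)
        assert np.isnan(r)

    def test_scale_invariance_on_fitted_model(self):
        design = balanced_design(8, 2)
        y = simulate_split_plot(design, 0.2, 0.4, seed=8, genotype_sd=0.8)
        r1 = lm.repeatability(design, y)
        r2 = lm.repeatability(design, 10.0 * y)
        np.testing.assert_allclose(r1.r, r2.r, atol=1e-5)
        assert 0.0 <= r1.r <= 1.0
        assert r1.n_irg == 2.0
        assert r1.se > 0
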