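import itertools

import numpy as np
import pandas as pd
import pytest

import leafmet as lm
from leafmet.stress_metabolome import volcano_table


def enumerate_mwu_p(x, y):
    """Exact two-sided Mann–Whitney p by exhausting every group split."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        return sum(np.sum(xi > ys) + 0.5 * np.sum(xi == ys) for xi in xs)

    u_obs = u_stat(range(nx))
    lo = min(u_obs, nx * (n - nx) - u_obs)
    hi = nx * (n - nx) - lo
    total = hits = 0
    for ix in itertools.combinations(range(n), nx):
        u = u_stat(ix)
        total += 1
        hits += int(u <= lo + 1e-9 or u >= hi - 1e-9)
    return hits / total


class TestImputation:
    def test_complete_table_unchanged(self, rng):
        table = pd.DataFrame(rng.random((6, 4)),
                             index=[f"s{i}" for i in range(6)],
                             columns=[f"m{i}" for i in range(4)])
        out = lm.impute_knn(table, k=3)
        pd.testing.assert_frame_equal(out, table)

    def test_equidistant_neighbours_average(self):
        # b and c sit symmetrically around a on the observed trait, so the
        # Gaussian kernel weights are equal and the fill is the plain mean
        table = pd.DataFrame(
            {"t1": [0.0, -1.0, 1.0], "t2": [np.nan, 4.0, 6.0]},
            index=["a", "b", "c"],
        )
        out = lm.impute_knn(table, k=2)
        np.testing.assert_allclose(out.loc["a", "t2"], 5.0)
        np.testing.assert_allclose(out.loc["b", "t2"], 4.0)  # observed untouched

    def test_generator_output_complete_after_imputation(self):
        sim = lm.SimConfig(n_metabolites=20, missing_rate=0.05, seed=3)
        design, truth = lm.generate_trial(sim)
        mets = lm.generate_metabolome(design, truth, sim)
        out = lm.impute_knn(mets, k=10)
        assert not out.isna().any().any()

    def test_k_too_large_rejected(self):
        table = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="k="):
            lm.impute_knn(table, k=3)

    def test_fully_missing_trait_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="missing in all"):
            lm.impute_knn(table, k=1)


class TestPCA:
    def test_perfectly_correlated_pair_puts_all_variance_on_pc1(self, rng):
        base = rng.random(20) + 0.5
        table = pd.DataFrame({"a": base, "b": 2.0 * base})
        res = lm.pca(table, log10=False)
        np.testing.assert_allclose(res.variance_fraction[0], 1.0, atol=1e-12)

    def test_fractions_sum_to_one_and_reconstruction(self, rng):
        table = pd.DataFrame(rng.gamma(4.0, 1.0, size=(15, 6)))
        res = lm.pca(table)
        np.testing.assert_allclose(res.variance_fraction.sum(), 1.0, atol=1e-10)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, res.processed.to_numpy(), atol=1e-8)
        # scores of distinct PCs orthogonal
        gram = res.scores.to_numpy().T @ res.scores.to_numpy()
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_independent_traits_split_variance(self, rng):
        table = pd.DataFrame(rng.normal(10.0, 1.0, size=(4000, 2)))
        res = lm.pca(table, log10=False)
        assert abs(res.variance_fraction[0] - 0.5) < 0.05

    def test_zero_variance_trait_dropped_with_warning(self, rng):
        table = pd.DataFrame({"a": rng.random(10) + 1, "b": np.ones(10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = lm.pca(table)
        assert list(res.loadings.index) == ["a"]

    def test_nonpositive_values_floored_under_log10(self, rng):
        table = pd.DataFrame({"a": np.r_[-1.0, rng.random(9) + 1.0],
                              "b": rng.random(10) + 1.0})
        with pytest.warns(UserWarning, match="floored"):
            lm.pca(table)


class TestMedianNormalization:
    def test_correction_factor_definition(self):
        # year A median 2, year B median 4 -> combined median 3
        a = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=["s1", "s2", "s3"])
        b = pd.DataFrame({"m": [3.0, 4.0, 5.0]}, index=["s1", "s2", "s3"])
        out = lm.median_normalize_across_years({2018: a, 2019: b})
        np.testing.assert_allclose(out.loc["2018_s2", "m"], 2.0 * (3.0 / 2.0))
        np.testing.assert_allclose(out.loc["2019_s2", "m"], 4.0 * (3.0 / 4.0))

    def test_identical_years_unchanged(self, rng):
        t = pd.DataFrame(rng.random((5, 3)) + 1.0, columns=list("abc"))
        out = lm.median_normalize_across_years({1: t, 2: t.copy()})
        np.testing.assert_allclose(out.iloc[:5].to_numpy(), t.to_numpy())

    def test_post_normalization_medians_equalized(self, rng):
        t1 = pd.DataFrame(rng.gamma(3, 1, (8, 4)) + 0.2, columns=list("abcd"))
        t2 = pd.DataFrame(5 * rng.gamma(3, 1, (8, 4)) + 0.2, columns=list("abcd"))
        out = lm.median_normalize_across_years({1: t1, 2: t2})
        overall = pd.concat([t1, t2]).median()
        y1 = out.iloc[:8].median()
        y2 = out.iloc[8:].median()
        np.testing.assert_allclose(y1, overall, rtol=1e-12)
        np.testing.assert_allclose(y2, overall, rtol=1e-12)

    def test_disjoint_traits_rejected(self):
        a = pd.DataFrame({"m1": [1.0]})
        b = pd.DataFrame({"m2": [1.0]})
        with pytest.raises(ValueError, match="shared"):
            lm.median_normalize_across_years({1: a, 2: b})


class TestClustering:
    def test_identical_rows_merge_at_zero(self, rng):
        v = rng.random(10)
        mat = pd.DataFrame([v, v, rng.random(10)], index=["a", "b", "c"])
        tree = lm.hcluster(mat)
        Z = tree["linkage"]
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_anticorrelated_rows_at_distance_two(self, rng):
        v = rng.random(12)
        mat = pd.DataFrame([v, -v], index=["a", "b"])
        tree = lm.hcluster(mat)
        np.testing.assert_allclose(tree["distances"][0], 2.0, atol=1e-12)

    def test_complete_linkage_merge_order_and_height(self, rng):
        # construct rows, then trace against the realized correlations
        a = rng.normal(size=200)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=200)
        c = rng.normal(size=200)
        mat = pd.DataFrame([a, b, c], index=["a", "b", "c"])
        corr = np.corrcoef(mat.to_numpy())
        tree = lm.hcluster(mat)
        Z = tree["linkage"]
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}  # the r~0.9 pair first
        expected_final = 1.0 - min(corr[0, 2], corr[1, 2])
        np.testing.assert_allclose(Z[1, 2], expected_final, atol=1e-12)

    def test_constant_row_rejected(self):
        mat = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["k", "m"])
        with pytest.raises(ValueError, match="constant"):
            lm.hcluster(mat)


class TestFoldChange:
    def test_ratio_of_group_means(self):
        table = pd.DataFrame({"m": [2.0, 2.0, 5.0, 5.0]},
                             index=["a", "b", "c", "d"])
        groups = pd.Series(["WW", "WW", "WL", "WL"], index=table.index)
        fc = lm.fold_change(table, groups)
        np.testing.assert_allclose(fc["m"], 2.5)

    def test_equal_means_give_unity(self, rng):
        v = rng.random(6) + 1
        table = pd.DataFrame({"m": np.r_[v, v]})
        table.index = [f"s{i}" for i in range(12)]
        groups = pd.Series(["WW"] * 6 + ["WL"] * 6, index=table.index)
        np.testing.assert_allclose(lm.fold_change(table, groups)["m"], 1.0)

    def test_scale_invariance(self, rng):
        table = pd.DataFrame(rng.random((8, 3)) + 0.5)
        table.index = [f"s{i}" for i in range(8)]
        groups = pd.Series(["WW"] * 4 + ["WL"] * 4, index=table.index)
        fc1 = lm.fold_change(table, groups)
        fc2 = lm.fold_change(table * 7.3, groups)
        np.testing.assert_allclose(fc1, fc2, rtol=1e-12)


class TestMannWhitney:
    def test_textbook_case(self):
        u, p = lm.mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-12)

    def test_identical_groups_p_one(self):
        _, p = lm.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.99

    @pytest.mark.parametrize("nx,ny", [(3, 3), (4, 5), (6, 6)])
    def test_exact_mode_matches_enumeration(self, nx, ny, rng):
        x = rng.normal(size=nx)
        y = rng.normal(size=ny) + 0.5
        _, p = lm.mann_whitney_u(x, y)
        np.testing.assert_allclose(p, enumerate_mwu_p(x, y), atol=1e-10)

    def test_normal_approximation_close_to_exact(self, rng):
        diffs = []
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            res_exact = enumerate_mwu_p(x, y)
            from scipy import stats
            res_approx = stats.mannwhitneyu(x, y, alternative="two-sided",
                                            method="asymptotic").pvalue
            diffs.append(abs(res_exact - res_approx))
        assert max(diffs) < 0.02


class TestBHAdjust:
    def brute_force_bh(self, p):
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, p[i] * m / rank_from_top)
            adj[i] = running
        return adj

    def test_stepwise_hand_example(self):
        adj = lm.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(lm.bh_adjust([0.37]), [0.37])

    def test_matches_brute_force_definition(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(lm.bh_adjust(p), self.brute_force_bh(p),
                                       atol=1e-14)

    def test_sorted_adjusted_nondecreasing(self, rng):
        p = rng.random(30)
        adj = lm.bh_adjust(p)
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()


class TestVolcano:
    def make_table(self, rng, fc=4.0, n_resp=2, n_total=10, n_per_group=8):
        ids = [f"s{i}" for i in range(2 * n_per_group)]
        groups = pd.Series(["WW"] * n_per_group + ["WL"] * n_per_group, index=ids)
        data = {}
        for j in range(n_total):
            base = rng.lognormal(0.0, 0.1, size=2 * n_per_group) + 1.0
            if j < n_resp:
                base[n_per_group:] *= fc
            data[f"m{j}"] = base
        return pd.DataFrame(data, index=ids), groups

    def test_category_rules(self):
        rec = pd.DataFrame({
            "FC": [3.0, 3.0, 0.3, 1.2],
            "p": [0.001, 0.05, 0.001, 0.001],
            "p_adj": [0.01, 0.20, 0.01, 0.01],
        }, index=["up", "ns", "down", "small_fc"])
        rec["category"] = np.where((rec.p_adj < 0.05) & (rec.FC < 0.5), "decrease",
                                   np.where((rec.p_adj < 0.05) & (rec.FC > 2), "increase", "none"))
        summary = lm.volcano_classify(rec)
        assert summary["n_increase"] == 1 and summary["n_decrease"] == 1
        np.testing.assert_allclose(summary["pct_regulated"], 50.0)
        np.testing.assert_allclose(summary["mean_fc_increase"], 3.0)

    def test_volcano_table_detects_planted_effects(self, rng):
        table, groups = self.make_table(rng)
        rec = volcano_table(table, groups)
        assert (rec.loc[["m0", "m1"], "category"] == "increase").all()
        assert (rec.loc["m5":, "category"] == "none").all()
        assert (rec["p_adj"] >= rec["p"] - 1e-15).all()

    def test_categories_invariant_to_common_rescaling(self, rng):
        table, groups = self.make_table(rng)
        r1 = volcano_table(table, groups)
        r2 = volcano_table(table * 13.7, groups)
        assert (r1["category"] == r2["category"]).all()
        np.testing.assert_allclose(r1["FC"], r2["FC"], rtol=1e-12)

    def test_class_summary_counts(self, rng):
        table, groups = self.make_table(rng)
        rec = volcano_table(table, groups)
        ann = pd.DataFrame({
            "trait_id": table.columns,
            "platform": "LC",
            "main_class": ["neutral lipids"] * 5 + ["terpenoids"] * 5,
            "subclass": ["TAG"] * 5 + ["triterpenoid"] * 5,
            "inchikey": "K",
        })
        summary = lm.volcano_classify(rec, ann)
        cs = summary["class_summary"]
        inc = cs[cs.category == "increase"]
        assert inc["n"].sum() == summary["n_increase"]
        assert set(inc["main_class"]) == {"neutral lipids"}
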