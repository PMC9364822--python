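"""Regression grid: oracle checks of the cluster-robust sandwich, trend
test behaviour, covariate-tier resolution, and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from fsamnps import (ModelSpec, descriptive_table, fit_linear, p_trend,
                     robust_cluster_vcov, run_table2)


def brute_force_cluster_vcov(X, y, groups):
    """Independent CRVE implementation: textbook sandwich with the
    Stata-style factor (G/(G-1)) * ((N-1)/(N-k))."""
    n, k = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    u = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((k, k))
    for g in np.unique(groups):
        s = X[groups == g].T @ u[groups == g]
        meat += np.outer(s, s)
    G = len(np.unique(groups))
    c = (G / (G - 1)) * ((n - 1) / (n - k))
    return c * bread @ meat @ bread


def analysis_frame(n=60, n_clusters=6, seed=0, beta=1.0, icc_sd=0.0):
    """Minimal analysis-ready table with a known linear signal."""
    rng = np.random.default_rng(seed)
    cluster = rng.integers(n_clusters, size=n)
    # with icc_sd > 0 both the exposure and the error are cluster-correlated,
    # so the naive OLS variance genuinely understates (Moulton effect)
    di = rng.normal(8, 2, size=n) + icc_sd * rng.normal(size=n_clusters)[cluster]
    noise = rng.normal(size=n) + icc_sd * rng.normal(size=n_clusters)[cluster]
    df = pd.DataFrame({
        "di_baseline": di,
        "glucose_baseline": 100 + beta * di + noise,
        "cluster_id": cluster,
    })
    df["di_baseline_tertile"] = pd.qcut(di, 3, labels=[1, 2, 3]).astype(int)
    return df


class TestFitLinear:
    def test_noiseless_exact_interpolation(self):
        df = analysis_frame(n=10)
        df["glucose_baseline"] = 2.0 * df["di_baseline"] + 3.0
        res = fit_linear(df, ModelSpec(outcome="glucose"))
        assert res.params.iloc[0]["beta"] == pytest.approx(2.0, abs=1e-10)
        assert res.r2 == pytest.approx(100.0)

    def test_robust_se_matches_brute_force_sandwich(self, toy_regression):
        df = toy_regression.rename(columns={
            "y": "glucose_baseline", "x": "di_baseline",
            "cluster": "cluster_id"})
        res = fit_linear(df, ModelSpec(outcome="glucose"))
        X = np.column_stack([np.ones(len(df)), df["di_baseline"]])
        V = brute_force_cluster_vcov(X, df["glucose_baseline"].to_numpy(),
                                     df["cluster_id"].to_numpy())
        assert res.params.iloc[0]["se"] == pytest.approx(
            np.sqrt(V[1, 1]), rel=1e-10)

    def test_point_estimates_invariant_to_robustification(self):
        df = analysis_frame(seed=1)
        robust = fit_linear(df, ModelSpec(outcome="glucose"))
        plain = sm.OLS(df["glucose_baseline"],
                       sm.add_constant(df["di_baseline"])).fit()
        assert robust.params.iloc[0]["beta"] == pytest.approx(
            plain.params.iloc[1], rel=1e-12)

    def test_ci_uses_normal_multiplier(self):
        df = analysis_frame(seed=2)
        res = fit_linear(df, ModelSpec(outcome="glucose"))
        row = res.params.iloc[0]
        assert row["ci_high"] - row["beta"] == pytest.approx(
            1.959964 * row["se"], rel=1e-5)

    def test_single_cluster_falls_back_to_hc(self):
        df = analysis_frame(seed=3)
        df["cluster_id"] = 0
        with pytest.warns(UserWarning, match="fewer than 2 clusters"):
            res = fit_linear(df, ModelSpec(outcome="glucose"))
        assert res.robust == "HC1"

    def test_rank_deficiency_names_columns(self):
        df = analysis_frame(seed=4)
        df["age"] = 60.0
        df["sex"] = "female"
        df["bmi_baseline"] = 2 * df["di_baseline"]  # explicit collinearity
        df["education"] = "primary"
        df["smoking"] = "never"
        df["energy_kcal"] = df["di_baseline"] * 2  # duplicate of bmi column
        df["pa_met_min_week"] = 100.0
        df["marital"] = "married"
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(df, ModelSpec(outcome="glucose", tier="model1"))


class TestRobustClusterVcov:
    def test_matches_brute_force(self, toy_regression):
        X = sm.add_constant(toy_regression["x"])
        fit = sm.OLS(toy_regression["y"], X).fit()
        V = robust_cluster_vcov(fit, toy_regression["cluster"])
        expected = brute_force_cluster_vcov(
            np.asarray(X), toy_regression["y"].to_numpy(),
            toy_regression["cluster"].to_numpy())
        assert np.allclose(V, expected, rtol=1e-10)

    def test_singleton_clusters_reduce_to_hc_type(self):
        rng = np.random.default_rng(7)
        X = sm.add_constant(rng.normal(size=12))
        y = rng.normal(size=12)
        fit = sm.OLS(y, X).fit()
        V = robust_cluster_vcov(fit, np.arange(12))
        # HC0 meat with singleton clusters, under the same correction factor
        u = fit.resid
        bread = np.linalg.inv(X.T @ X)
        meat = X.T @ np.diag(u**2) @ X
        n, k = X.shape
        c = (n / (n - 1)) * ((n - 1) / (n - k))
        assert np.allclose(V, c * bread @ meat @ bread, rtol=1e-10)

    def test_duplicated_rows_leave_beta_unchanged(self):
        df = analysis_frame(seed=8)
        dup = pd.concat([df, df], ignore_index=True)
        b1 = fit_linear(df, ModelSpec(outcome="glucose")).params.iloc[0]["beta"]
        b2 = fit_linear(dup, ModelSpec(outcome="glucose")).params.iloc[0]["beta"]
        assert b1 == pytest.approx(b2, rel=1e-12)

    def test_within_cluster_correlation_inflates_se(self):
        df = analysis_frame(n=400, n_clusters=10, seed=9, icc_sd=3.0)
        # cluster-correlated errors: the naive OLS SE understates
        res = fit_linear(df, ModelSpec(outcome="glucose"))
        naive = sm.OLS(df["glucose_baseline"],
                       sm.add_constant(df["di_baseline"])).fit()
        assert res.params.iloc[0]["se"] > 1.2 * naive.bse.iloc[1]


class TestPTrend:
    def test_monotone_signal_gives_tiny_p(self):
        df = analysis_frame(n=300, seed=10)
        df["glucose_baseline"] = (100 + 5 * df["di_baseline_tertile"]
                                  + 0.01 * np.random.default_rng(0).normal(size=300))
        spec = ModelSpec(outcome="glucose", exposure="tertile")
        assert p_trend(df, spec) < 1e-10

    def test_affine_invariance_of_ordinal_coding(self):
        df = analysis_frame(n=120, seed=11)
        spec = ModelSpec(outcome="glucose", exposure="tertile")
        p123 = p_trend(df, spec)
        shifted = df.copy()
        shifted["di_baseline_tertile"] = df["di_baseline_tertile"] - 1
        assert p_trend(shifted, spec) == pytest.approx(p123, rel=1e-9)

    def test_null_p_roughly_uniform(self):
        """Under independence the trend p is ~U(0,1) over replications."""
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(120):
            df = analysis_frame(n=90, n_clusters=90,
                                seed=rng.integers(2**31), beta=0.0)
            df["glucose_baseline"] = rng.normal(size=90)
            ps.append(p_trend(df, ModelSpec(outcome="glucose",
                                            exposure="tertile")))
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


class TestModelSpecCovariates:
    def test_model1_covariate_set(self):
        cols = [c for c, _ in ModelSpec(outcome="glucose",
                                        tier="model1").covariate_terms()]
        assert cols == ["age", "sex", "bmi_baseline", "education", "smoking",
                        "energy_kcal", "pa_met_min_week", "marital"]

    @pytest.mark.parametrize("outcome", ["bmi", "waist"])
    def test_bmi_dropped_for_adiposity_outcomes(self, outcome):
        cols = [c for c, _ in ModelSpec(outcome=outcome,
                                        tier="full").covariate_terms()]
        assert "bmi_baseline" not in cols

    def test_prospective_adds_baseline_level_and_arm(self):
        spec = ModelSpec(outcome="glucose", tier="full",
                         analysis="prospective")
        cols = [c for c, _ in spec.covariate_terms()]
        assert "glucose_baseline" in cols and "arm" in cols
        cross = ModelSpec(outcome="glucose", tier="full")
        assert "arm" not in [c for c, _ in cross.covariate_terms()]
        m1 = ModelSpec(outcome="glucose", tier="model1",
                       analysis="prospective")
        assert "arm" not in [c for c, _ in m1.covariate_terms()]


class TestDescriptiveTable:
    @staticmethod
    def frame():
        rng = np.random.default_rng(13)
        n = 90
        return pd.DataFrame({
            "di_baseline_tertile": np.repeat([1, 2, 3], n // 3),
            "age": rng.normal(65, 5, n),
            "tg": rng.lognormal(4.9, 0.3, n),
            "sex": rng.choice(["male", "female"], n),
        })

    def test_chi_square_matches_hand_computation(self):
        df = self.frame()
        table = descriptive_table(df, {"sex": "categorical"})
        counts = pd.crosstab(df["sex"], df["di_baseline_tertile"]).to_numpy()
        expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        dof = (counts.shape[0] - 1) * (counts.shape[1] - 1)
        p_hand = scipy.stats.chi2.sf(chi2, dof)
        assert table["p"].iloc[0] == pytest.approx(p_hand, rel=1e-9)

    def test_anova_matches_scipy_and_identical_groups_give_f0(self):
        df = self.frame()
        table = descriptive_table(df, {"age": "continuous"})
        groups = [g["age"].to_numpy()
                  for _, g in df.groupby("di_baseline_tertile")]
        assert table["p"].iloc[0] == pytest.approx(
            scipy.stats.f_oneway(*groups).pvalue)
        same = df.copy()
        same["age"] = np.tile(df["age"].iloc[:30].to_numpy(), 3)
        t2 = descriptive_table(same, {"age": "continuous"})
        assert t2["p"].iloc[0] == pytest.approx(1.0)

    def test_structure_median_and_rowcount(self):
        df = self.frame()
        table = descriptive_table(
            df, {"age": "continuous", "tg": "median", "sex": "categorical"})
        assert set(table["variable"]) == {"age", "tg", "sex"}
        # one row per tertile for continuous/median, per level x tertile for
        # categorical
        assert len(table) == 3 + 3 + 2 * 3
        assert "[" in table.loc[table["variable"] == "tg", "summary"].iloc[0]


def test_run_table2_structure(small_cohort):
    from fsamnps import build_analysis_table
    table, _ = build_analysis_table(
        small_cohort.composition, small_cohort.responses,
        small_cohort.participants, small_cohort.measurements)
    grid = run_table2(table)
    assert set(grid["outcome"]) == {"glucose", "hdl", "tg", "ldl", "dbp",
                                    "sbp", "bmi", "waist"}
    # 8 outcomes x 3 tiers x (T2, T3, continuous)
    assert len(grid) == 8 * 3 * 3
    per = grid[(grid["outcome"] == "glucose") & (grid["tier"] == "model1")]
    assert set(per["term"]) == {"T2", "T3", "continuous"}
    # continuous and tertile analyses share the row set per outcome-tier
    assert per["n"].nunique() == 1
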