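"""Statistical engine: centering, design, pointwise GLM, FDR, summary ANOVA, power."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from ccmorph.contour_io import SubjectRecord, records_to_frame
from ccmorph.geometry import profiles_to_cdv
from ccmorph.stats import (
    AnalysisConfig,
    DesignError,
    adjusted_group_means,
    anova_from_summary,
    anova_power,
    bh_fdr,
    build_design,
    center_within_group,
    fit_pointwise_omnibus,
    fit_pointwise_posthoc,
)


def make_records(n_per_group=6, groups=("OCD", "SZ", "BD", "MDD", "HC"), seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for g in groups:
        for j in range(n_per_group):
            hc = g == "HC"
            recs.append(
                SubjectRecord(
                    subject_id=f"{g}{j}",
                    diagnosis=g,
                    sex="M" if j % 2 == 0 else "F",
                    age=float(rng.uniform(20, 60)),
                    education=float(rng.uniform(8, 20)),
                    tiv=float(rng.uniform(1200, 1700)),
                    illness_duration=None if hc else float(rng.uniform(1, 30)),
                    cpz=None if hc else float(rng.uniform(0, 300)),
                )
            )
    return recs


class TestCenterWithinGroup:
    def test_mean_removal(self):
        out = center_within_group([10, 20, 30], ["A", "A", "A"])
        np.testing.assert_allclose(out, [-10, 0, 10])

    def test_controls_pinned_at_zero(self):
        out = center_within_group([5.0, 7.0], ["HC", "HC"])
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_groups_centered_independently(self):
        out = center_within_group([1, 3, 10, 30], ["A", "A", "B", "B"])
        np.testing.assert_allclose(out, [-1, 1, -10, 10])

    def test_absent_imputed_at_group_mean(self):
        out = center_within_group([1.0, np.nan, 3.0], ["A", "A", "A"])
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])

    def test_all_absent_group_is_degenerate(self):
        with pytest.raises(ValueError, match="absent"):
            center_within_group([np.nan, np.nan], ["A", "A"])

    def test_per_group_mean_of_centered_values_is_zero(self):
        rng = np.random.default_rng(2)
        groups = np.repeat(["A", "B", "C", "HC"], 25)
        values = rng.normal(50, 20, 100)
        values[rng.random(100) < 0.2] = np.nan
        values[groups == "HC"] = np.nan
        out = center_within_group(values, groups)
        for g in ("A", "B", "C"):
            present = (groups == g) & np.isfinite(values)
            assert abs(out[present].mean()) < 1e-12


class TestBuildDesign:
    def test_column_count_full_model(self):
        design = build_design(make_records())
        assert design.X.shape == (30, 10)  # 1 + 4 contrasts + 5 covariates
        assert design.reference == "HC"
        assert len(design.group_columns) == 4

    def test_patient_contrast_uses_raw_clinical_values(self):
        recs = make_records()
        design = build_design(recs, AnalysisConfig(), contrast_groups=("OCD", "SZ"))
        df = records_to_frame(recs)
        df = df[df["diagnosis"].isin(["OCD", "SZ"])]
        j = design.columns.index("illness_duration")
        np.testing.assert_allclose(
            design.X[:, j], df["illness_duration_years"].to_numpy()
        )

    def test_control_contrast_centers_clinical_values(self):
        design = build_design(make_records(), AnalysisConfig(),
                              contrast_groups=("OCD", "HC"))
        j = design.columns.index("cpz")
        col = design.X[:, j]
        hc = np.asarray(design.groups) == "HC"
        np.testing.assert_array_equal(col[hc], 0.0)
        assert abs(col[~hc].mean()) < 1e-12

    def test_collinear_columns_named(self):
        recs = [
            SubjectRecord(f"s{j}{g}", g, "M", age=30 + j, education=10.0,
                          tiv=1000.0 + (30 + j),  # tiv - age is constant -> collinear
                          illness_duration=None if g == "HC" else 5.0,
                          cpz=None if g == "HC" else 10.0)
            for j in range(8) for g in ("OCD", "HC")
        ]
        with pytest.raises(DesignError, match="tiv"):
            build_design(recs)

    def test_sex_never_in_design(self):
        design = build_design(make_records())
        assert not any("sex" in c.lower() for c in design.columns)


def elimination_ols_rss(X, y):
    """Independent oracle: normal equations solved by Gaussian elimination."""
    XtX = [[sum(X[i][a] * X[i][b] for i in range(len(X))) for b in range(len(X[0]))]
           for a in range(len(X[0]))]
    Xty = [sum(X[i][a] * y[i] for i in range(len(X))) for a in range(len(X[0]))]
    p = len(XtX)
    A = [row[:] + [rhs] for row, rhs in zip(XtX, Xty)]
    for col in range(p):
        piv = max(range(col, p), key=lambda r: abs(A[r][col]))
        A[col], A[piv] = A[piv], A[col]
        for r in range(p):
            if r != col and A[col][col] != 0:
                fac = A[r][col] / A[col][col]
                A[r] = [a - fac * b for a, b in zip(A[r], A[col])]
    beta = [A[i][p] / A[i][i] for i in range(p)]
    return sum(
        (y[i] - sum(X[i][j] * beta[j] for j in range(p))) ** 2
        for i in range(len(X))
    )


class TestPointwiseOmnibus:
    def test_degrees_of_freedom_bookkeeping(self):
        recs = make_records(n_per_group=30)
        design = build_design(recs)
        rng = np.random.default_rng(1)
        cdv = pd.DataFrame(
            rng.normal(2.5, 0.3, (150, 10)),
            index=[r.subject_id for r in recs],
            columns=range(1, 11),
        )
        res = fit_pointwise_omnibus(cdv, design, AnalysisConfig(n_points=10))
        assert (res["df1"] == 4).all()
        assert (res["df2"] == 140).all()
        assert len(res) == 10

    def test_f_matches_elimination_oracle(self):
        """Single position, 20 subjects: F equals a hand-rolled
        normal-equations least-squares computation to 1e-8."""
        recs = make_records(n_per_group=5, groups=("OCD", "SZ", "BD", "HC"), seed=4)
        design = build_design(
            recs, AnalysisConfig(covariates=("age", "tiv"))
        )
        rng = np.random.default_rng(8)
        y = rng.normal(3.0, 0.5, 20)
        cdv = pd.DataFrame(
            y[:, None], index=[r.subject_id for r in recs], columns=[1]
        )
        res = fit_pointwise_omnibus(cdv, design, AnalysisConfig(covariates=("age", "tiv")))

        X_full = design.X.tolist()
        keep = [i for i, c in enumerate(design.columns) if c not in design.group_columns]
        X_red = design.X[:, keep].tolist()
        rss_f = elimination_ols_rss(X_full, y.tolist())
        rss_r = elimination_ols_rss(X_red, y.tolist())
        df1, df2 = 3, 20 - len(design.columns)
        expected = ((rss_r - rss_f) / df1) / (rss_f / df2)
        assert res["statistic"].iloc[0] == pytest.approx(expected, abs=1e-8)

    def test_f_matches_statsmodels(self):
        recs = make_records(n_per_group=8, seed=5)
        design = build_design(recs)
        rng = np.random.default_rng(9)
        y = rng.normal(3.0, 0.4, len(recs))
        cdv = pd.DataFrame(y[:, None], index=[r.subject_id for r in recs], columns=[1])
        res = fit_pointwise_omnibus(cdv, design)
        fit = sm.OLS(y, design.X).fit()
        contrast = np.zeros((4, design.X.shape[1]))
        for r, c in enumerate(design.group_columns):
            contrast[r, design.columns.index(c)] = 1.0
        ftest = fit.f_test(contrast)
        assert res["statistic"].iloc[0] == pytest.approx(float(ftest.fvalue), rel=1e-10)
        assert res["p_raw"].iloc[0] == pytest.approx(float(ftest.pvalue), rel=1e-8)

    def test_intercept_absorbs_constant_shifts(self):
        recs = make_records(n_per_group=10, seed=6)
        design = build_design(recs)
        rng = np.random.default_rng(10)
        Y = rng.normal(3.0, 0.4, (len(recs), 5))
        idx = [r.subject_id for r in recs]
        a = fit_pointwise_omnibus(pd.DataFrame(Y, index=idx, columns=range(1, 6)),
                                  design, AnalysisConfig(n_points=5))
        b = fit_pointwise_omnibus(pd.DataFrame(Y + 17.3, index=idx, columns=range(1, 6)),
                                  design, AnalysisConfig(n_points=5))
        np.testing.assert_allclose(a["statistic"], b["statistic"], rtol=1e-9)

    def test_posthoc_f_is_squared_t(self):
        recs = make_records(n_per_group=12, seed=7)
        rng = np.random.default_rng(12)
        cdv = pd.DataFrame(
            rng.normal(2.5, 0.3, (len(recs), 3)),
            index=[r.subject_id for r in recs], columns=range(1, 4),
        )
        res = fit_pointwise_posthoc(cdv, recs, "OCD", "HC",
                                    AnalysisConfig(n_points=3))
        assert (res["df1"] == 1).all()
        design = build_design(recs, AnalysisConfig(), contrast_groups=("OCD", "HC"))
        j = design.columns.index("diagnosis[OCD]")
        for pos in range(1, 4):
            y = cdv.loc[list(design.subject_ids), pos].to_numpy()
            t = sm.OLS(y, design.X).fit().tvalues[j]
            assert res["statistic"].iloc[pos - 1] == pytest.approx(t**2, abs=1e-10)


def brute_force_step_up(p, q):
    """Independent oracle: test every cutoff k explicitly and reject the k
    smallest p-values for the largest k with p_(k) <= k*q/m."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            best_k = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:best_k]] = True
    return reject


class TestBhFdr:
    def test_all_ones_reject_nothing(self):
        p_adj, reject = bh_fdr(np.ones(7))
        np.testing.assert_array_equal(p_adj, 1.0)
        assert not reject.any()

    def test_hand_applied_step_up(self):
        p_adj, reject = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.25], q=0.05)
        np.testing.assert_array_equal(reject, [True, True, True, True, False])
        np.testing.assert_allclose(p_adj, [0.05, 0.05, 0.05, 0.05, 0.25])

    def test_domain_error(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
        st.sampled_from([0.01, 0.05, 0.1, 0.2]),
    )
    def test_matches_brute_force_cutoff_oracle(self, p, q):
        _, reject = bh_fdr(p, q)
        np.testing.assert_array_equal(reject, brute_force_step_up(p, q))

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(15)
        p = rng.beta(0.4, 3.0, 300)
        p_adj, reject = bh_fdr(p, q=0.05)
        sm_reject, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(p_adj, sm_adj, atol=1e-12)
        np.testing.assert_array_equal(reject, sm_reject)

    def test_by_variant_matches_statsmodels(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(0, 1, 120)
        p_adj, _ = bh_fdr(p, q=0.05, method="by")
        _, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_by")
        np.testing.assert_allclose(p_adj, sm_adj, atol=1e-12)

    def test_rejections_monotone_in_q(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(0, 1, 200) ** 2
        _, r_low = bh_fdr(p, q=0.01)
        _, r_high = bh_fdr(p, q=0.05)
        assert not np.any(r_low & ~r_high)


class TestAnovaFromSummary:
    def test_equal_means_give_zero_f(self):
        F, df1, df2, p = anova_from_summary([5, 5, 5], [1, 2, 3], [10, 10, 10])
        assert F == 0.0 and df1 == 2 and df2 == 27 and p == 1.0

    def test_degenerate_all_zero_sds_equal_means(self):
        with pytest.raises(ValueError, match="undefined"):
            anova_from_summary([5, 5], [0, 0], [10, 10])

    def test_agrees_with_raw_data_omnibus(self):
        """Summary-statistics ANOVA must reproduce the pointwise omnibus F
        computed from the raw data when there are no covariates."""
        rng = np.random.default_rng(18)
        groups = ("OCD", "SZ", "HC")
        recs = make_records(n_per_group=10, groups=groups, seed=18)
        y = rng.normal(3.0, 0.5, 30) + np.repeat([0.0, 0.2, 0.4], 10)
        design = build_design(recs, AnalysisConfig(covariates=()))
        cdv = pd.DataFrame(y[:, None], index=[r.subject_id for r in recs], columns=[1])
        res = fit_pointwise_omnibus(cdv, design, AnalysisConfig(covariates=()))
        labels = np.array([r.diagnosis for r in recs])
        y_aligned = cdv.loc[list(design.subject_ids), 1].to_numpy()
        glab = np.array(design.groups)
        means = [y_aligned[glab == g].mean() for g in groups]
        sds = [y_aligned[glab == g].std(ddof=1) for g in groups]
        F, df1, df2, _ = anova_from_summary(means, sds, [10, 10, 10])
        assert F == pytest.approx(res["statistic"].iloc[0], abs=1e-8)


class TestAdjustedGroupMeans:
    def test_reduces_to_raw_means_without_covariates(self):
        recs = make_records(n_per_group=9, seed=19)
        rng = np.random.default_rng(19)
        Y = rng.normal(3.0, 0.4, (len(recs), 4))
        cdv = pd.DataFrame(Y, index=[r.subject_id for r in recs], columns=range(1, 5))
        config = AnalysisConfig(covariates=())
        design = build_design(recs, config)
        means = adjusted_group_means(cdv, design, config)
        glab = np.array(design.groups)
        Y_aligned = cdv.loc[list(design.subject_ids)].to_numpy()
        for g in sorted(set(glab)):
            raw = Y_aligned[glab == g].mean(axis=0)
            got = means[means["group"] == g].sort_values("position")[
                "adjusted_mean_cdv_mm"].to_numpy()
            np.testing.assert_allclose(got, raw, atol=1e-10)


class TestParameterRecovery:
    def test_contiguous_thinning_window_recovered_after_fdr(self):
        """A 20% thinning injected at positions 20-80 in a 30-vs-30
        case-control contrast is recovered at >= 90% of injected positions
        after FDR, with <= 5% of uninjected positions flagged on average
        over 10 simulation seeds."""
        from ccmorph.geometry import compute_profile
        from ccmorph.synthetic import EffectMap, SimulationConfig, simulate_cohort
        from ccmorph.geometry import profiles_to_cdv

        eff = np.ones(100)
        eff[19:80] = 0.8
        effects = EffectMap({"OCD": eff})
        injected = set(range(20, 81))
        recovery, fp = [], []
        for seed in range(10):
            pairs, records = simulate_cohort(
                SimulationConfig(seed=seed, groups=("OCD", "HC")), effects
            )
            cdv = profiles_to_cdv(compute_profile(p) for p in pairs)
            res = fit_pointwise_posthoc(cdv, records, "OCD", "HC")
            sig = set(res.loc[res["significant"], "position"])
            recovery.append(len(sig & injected) / len(injected))
            fp.append(len(sig - injected) / (100 - len(injected)))
        assert np.mean(recovery) >= 0.90
        assert np.mean(fp) <= 0.05

    def test_identical_groups_yield_almost_no_rejections(self):
        """Two groups simulated from identical parameters produce nearly
        empty significance maps across seeds."""
        from ccmorph.geometry import compute_profile, profiles_to_cdv
        from ccmorph.synthetic import EffectMap, SimulationConfig, simulate_cohort

        counts = []
        for seed in range(5):
            pairs, records = simulate_cohort(
                SimulationConfig(seed=seed, groups=("BD", "MDD")), EffectMap({})
            )
            cdv = profiles_to_cdv(compute_profile(p) for p in pairs)
            res = fit_pointwise_posthoc(cdv, records, "BD", "MDD")
            counts.append(int(res["significant"].sum()))
        assert np.mean(counts) <= 5.0


class TestAnovaPower:
    def test_null_effect_power_equals_alpha(self):
        assert anova_power(5, 150, 0.0, alpha=0.05) == 0.05

    def test_strictly_increasing_in_sample_size(self):
        powers = [anova_power(5, n, 0.25) for n in (50, 100, 150, 300)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_covariates_consume_error_df(self):
        assert anova_power(5, 150, 0.25, n_covariates=5) < anova_power(5, 150, 0.25)

    def test_invalid_dfs(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            anova_power(5, 8, 0.25, n_covariates=5)
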