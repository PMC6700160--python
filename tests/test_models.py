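"""Linear-model layer: OLS oracle checks, F/t statistics, variance moderation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import npcomics as n
from npcomics.models import (DesignMatrix, RankError, build_design_matrix,
                             contrast_t_statistics, f_pvalues, fit_matrix,
                             group_f_statistics, moderate_variances)


_IRREGULAR_AGES = [31.0, 44.0, 28.0, 52.0, 39.0, 47.0, 35.0, 58.0, 42.0,
                   30.0, 55.0, 37.0, 49.0, 33.0, 61.0]


def _design_rows(groups, sexes=None, ages=None):
    n_s = len(groups)
    sexes = sexes or ["F", "M"] * (n_s // 2 + 1)
    ages = ages if ages is not None else _IRREGULAR_AGES
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_s)],
        "individual_id": [f"i{i}" for i in range(n_s)],
        "dataset_id": "CD4", "group": groups,
        "age": ages[:n_s], "sex": sexes[:n_s]})


class TestBuildDesignMatrix:
    def test_three_groups_two_sexes_give_five_columns(self):
        rows = _design_rows(["HC", "HC", "RR", "RR", "SP", "SP"])
        dm = build_design_matrix(rows)
        assert dm.columns == ["intercept", "groupRR", "groupSP", "age", "sexM"]
        assert dm.group_cols == [1, 2]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            build_design_matrix(_design_rows(["HC"] * 6))

    def test_constant_age_dropped_with_warning(self, caplog):
        rows = _design_rows(["HC", "HC", "HC", "RR", "RR", "RR"],
                            ages=[40.0] * 6)
        with caplog.at_level("WARNING"):
            dm = build_design_matrix(rows)
        assert "age" not in dm.columns
        assert "zero variance" in caplog.text

    def test_group_confounded_with_sex_raises_rank_error(self):
        rows = _design_rows(["HC", "HC", "HC", "RR", "RR", "RR"],
                            sexes=["M", "M", "M", "F", "F", "F"],
                            ages=[31.0, 35, 39, 33, 36, 41])
        with pytest.raises(RankError, match="collinear"):
            build_design_matrix(rows)

    def test_age_is_mean_centred(self):
        rows = _design_rows(["HC", "HC", "RR", "RR", "SP", "SP"])
        dm = build_design_matrix(rows)
        assert abs(dm.X[:, dm.columns.index("age")].sum()) < 1e-9


class TestFitFeatureModels:
    def test_noiseless_response_recovers_coefficients_exactly(self, rng):
        rows = _design_rows(["HC", "HC", "RR", "RR", "SP", "SP", "HC", "RR"])
        dm = build_design_matrix(rows)
        beta = rng.normal(size=(3, dm.p))
        Y = beta @ dm.X.T
        fits = fit_matrix(Y, dm)
        np.testing.assert_allclose(fits.coef, beta, atol=1e-9)
        np.testing.assert_allclose(fits.sigma2, 0.0, atol=1e-18)

    def test_intercept_only_variance_matches_hand_ols(self):
        dm = DesignMatrix(X=np.ones((4, 1)), columns=["intercept"],
                          sample_ids=list("abcd"), group_cols=[])
        fits = fit_matrix(np.array([[1.0, 2.0, 3.0, 4.0]]), dm)
        assert fits.coef[0, 0] == pytest.approx(2.5)
        assert fits.sigma2[0] == pytest.approx(5.0 / 3.0)

    def test_coefficients_match_per_feature_normal_equations(self, rng):
        rows = _design_rows(list("HC RR SP".split() * 4)[:10])
        dm = build_design_matrix(rows)
        Y = rng.normal(size=(25, dm.n))
        fits = fit_matrix(Y, dm)
        for f in range(Y.shape[0]):
            b = np.linalg.solve(dm.X.T @ dm.X, dm.X.T @ Y[f])
            np.testing.assert_allclose(fits.coef[f], b, rtol=1e-8)
            r = Y[f] - dm.X @ b
            np.testing.assert_allclose(fits.sigma2[f],
                                       (r ** 2).sum() / (dm.n - dm.p), rtol=1e-8)

    def test_too_few_samples_rejected(self):
        dm = DesignMatrix(X=np.ones((1, 1)), columns=["intercept"],
                          sample_ids=["a"], group_cols=[])
        with pytest.raises(ValueError, match="residual df"):
            fit_matrix(np.array([[1.0]]), dm)


class TestGroupFStatistics:
    @pytest.fixture()
    def fitted(self, rng):
        rows = _design_rows(["HC", "HC", "HC", "RR", "RR", "RR", "SP", "SP",
                             "SP", "HC", "RR", "SP"])
        dm = build_design_matrix(rows)
        Y = rng.normal(size=(30, dm.n))
        return fit_matrix(Y, dm), dm

    def test_zero_group_effect_zero_noise_gives_zero_f(self):
        rows = _design_rows(["HC", "HC", "RR", "RR", "SP", "SP", "HC", "RR"])
        dm = build_design_matrix(rows)
        beta = np.zeros((2, dm.p))
        beta[:, 0] = 3.0                         # intercept
        beta[:, dm.columns.index("age")] = 0.5   # covariate effect only
        fits = fit_matrix(beta @ dm.X.T, dm)
        np.testing.assert_allclose(group_f_statistics(fits, dm), 0.0)

    def test_matches_full_vs_reduced_rss_brute_force(self, fitted):
        fits, dm = fitted
        Y = fits.coef @ dm.X.T  # reconstructable? use fresh data instead
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(20, dm.n))
        fits = fit_matrix(Y, dm)
        F = group_f_statistics(fits, dm)
        red = np.delete(dm.X, dm.group_cols, axis=1)
        for f in range(Y.shape[0]):
            rss = []
            for X in (dm.X, red):
                b, *_ = np.linalg.lstsq(X, Y[f], rcond=None)
                rss.append(((Y[f] - X @ b) ** 2).sum())
            expect = ((rss[1] - rss[0]) / 2) / (rss[0] / (dm.n - dm.p))
            assert F[f] == pytest.approx(expect, rel=1e-8)

    def test_two_group_f_equals_squared_t(self, rng):
        rows = _design_rows(["HC"] * 6 + ["RR"] * 6)
        dm = build_design_matrix(rows)
        fits = fit_matrix(rng.normal(size=(15, dm.n)), dm)
        F = group_f_statistics(fits, dm)
        t = contrast_t_statistics(fits, dm, "HC-RR")["t"].to_numpy()
        np.testing.assert_allclose(F, t ** 2, rtol=1e-9)

    def test_invariant_to_constant_shift_of_feature(self, fitted):
        fits, dm = fitted
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(10, dm.n))
        F1 = group_f_statistics(fit_matrix(Y, dm), dm)
        F2 = group_f_statistics(fit_matrix(Y + 42.0, dm), dm)
        np.testing.assert_allclose(F1, F2, rtol=1e-6)

    def test_invariant_to_joint_sample_permutation(self, rng):
        rows = _design_rows(["HC", "HC", "HC", "RR", "RR", "RR", "SP", "SP",
                             "SP", "HC", "RR", "SP"])
        Y = rng.normal(size=(10, len(rows)))
        order = rng.permutation(len(rows))
        dm1 = build_design_matrix(rows)
        dm2 = build_design_matrix(rows.iloc[order].reset_index(drop=True))
        F1 = group_f_statistics(fit_matrix(Y, dm1), dm1)
        F2 = group_f_statistics(fit_matrix(Y[:, order], dm2), dm2)
        np.testing.assert_allclose(F1, F2, rtol=1e-8)

    def test_parametric_pvalues_uniform_under_global_null(self):
        cfg = n.StudyConfig(n_hc=10, n_rr=10, n_sp=8, paired_fraction=0.7,
                            n_genes=5000, n_probes=0)
        study = n.simulate_study(cfg, seed=21)
        data = study.expression["CD4"]
        rows = study.design.subset("CD4").set_index("sample_id") \
            .loc[data.sample_ids].reset_index()
        dm = build_design_matrix(rows)
        fits = n.fit_feature_models(data, dm)
        p = f_pvalues(group_f_statistics(fits, dm), fits, dm)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestContrastT:
    def test_injected_shift_gives_large_positive_t(self, rng):
        rows = _design_rows(["HC"] * 5 + ["RR"] * 5 + ["SP"] * 5)
        dm = build_design_matrix(rows)
        y = 0.001 * rng.normal(size=(1, dm.n))
        y[0, 5:10] += 1.0  # upregulated in RR
        fits = fit_matrix(y, dm)
        t = contrast_t_statistics(fits, dm, "HC-RR")["t"].iloc[0]
        assert t > 50

    def test_equal_rr_sp_coefficients_give_zero_t_noiseless(self):
        rows = _design_rows(["HC"] * 4 + ["RR"] * 4 + ["SP"] * 4)
        dm = build_design_matrix(rows)
        beta = np.zeros((1, dm.p))
        beta[0, dm.columns.index("groupRR")] = 0.7
        beta[0, dm.columns.index("groupSP")] = 0.7
        fits = fit_matrix(beta @ dm.X.T, dm)
        assert contrast_t_statistics(fits, dm, "RR-SP")["t"].iloc[0] == 0.0

    def test_matches_brute_force_contrast_formula(self, rng):
        rows = _design_rows(["HC", "RR", "SP"] * 4)
        dm = build_design_matrix(rows)
        Y = rng.normal(size=(12, dm.n))
        fits = fit_matrix(Y, dm)
        for contrast in ("HC-RR", "RR-SP"):
            c = np.zeros(dm.p)
            c[dm.columns.index("groupRR")] = 1.0 if contrast == "HC-RR" else -1.0
            if contrast == "RR-SP":
                c[dm.columns.index("groupSP")] = 1.0
            tab = contrast_t_statistics(fits, dm, contrast)
            xtx_inv = np.linalg.inv(dm.X.T @ dm.X)
            for f in range(Y.shape[0]):
                b = np.linalg.solve(dm.X.T @ dm.X, dm.X.T @ Y[f])
                s2 = ((Y[f] - dm.X @ b) ** 2).sum() / (dm.n - dm.p)
                expect = (c @ b) / np.sqrt(s2 * c @ xtx_inv @ c)
                assert tab["t"].iloc[f] == pytest.approx(expect, rel=1e-8)


class TestModerateVariances:
    def _fits(self, sigma2, df=10):
        nf = len(sigma2)
        return n.ModelFits(coef=np.zeros((nf, 2)), sigma2=np.asarray(sigma2),
                           df_resid=df, xtx_inv=np.eye(2),
                           columns=["intercept", "groupRR"],
                           feature_ids=[f"f{i}" for i in range(nf)])

    def test_disabled_is_identity(self, rng):
        fits = self._fits(rng.chisquare(5, size=100) / 5)
        out = moderate_variances(fits, enabled=False)
        assert out is fits

    def test_identical_variances_shrink_to_themselves(self):
        fits = self._fits(np.full(200, 2.0))
        out = moderate_variances(fits, enabled=True)
        np.testing.assert_allclose(out.sigma2_mod, 2.0, rtol=1e-6)

    def test_shrinkage_moves_variances_toward_common_point(self):
        rng = np.random.default_rng(7)
        df, d0 = 10, 4.0
        sigma2 = (rng.chisquare(df, 800) / df) / (rng.chisquare(d0, 800) / d0)
        fits = self._fits(sigma2, df=df)
        out = moderate_variances(fits, enabled=True)
        assert np.isfinite(out.df_prior) and out.df_prior > 0
        s0_sq = (out.sigma2_mod * (out.df_prior + df)
                 - df * fits.sigma2)[0] / out.df_prior
        # moderated variance sits between the observed value and the prior
        lo = np.minimum(fits.sigma2, s0_sq)
        hi = np.maximum(fits.sigma2, s0_sq)
        assert ((out.sigma2_mod >= lo - 1e-9) & (out.sigma2_mod <= hi + 1e-9)).all()
        # and the ranking of features by variance is preserved
        assert (np.argsort(out.sigma2_mod) == np.argsort(fits.sigma2)).all()

    def test_prior_df_recovered_from_scaled_inv_chisq_sample(self):
        # s2 ~ s0^2 * (chi2_df/df) / (chi2_d0/d0) with d0=4, s0^2=1
        rng = np.random.default_rng(123)
        d0, s0_sq, df, nf = 4.0, 1.0, 10, 5000
        sigma2 = (s0_sq * (rng.chisquare(df, nf) / df)
                  / (rng.chisquare(d0, nf) / d0))
        out = moderate_variances(self._fits(sigma2, df=df), enabled=True)
        assert 2.5 <= out.df_prior <= 6.5

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError, match="50 features"):
            moderate_variances(self._fits(np.ones(10)), enabled=True)


class TestAssignExpressionGroups:
    @staticmethod
    def _tstats(values):
        out = {}
        for ds, by_ct in values.items():
            out[ds] = {ct: pd.DataFrame({"feature_id": ["f"], "t": [v],
                                         "effect": [v]})
                       for ct, v in by_ct.items()}
        return out

    @pytest.mark.parametrize("cd4, cd8, expected", [
        ((2.0, 1.5), (1.0, 0.5), "G1"),    # up in RR, up in SP, concordant
        ((2.0, -1.5), (1.0, -0.5), "G2"),
        ((-2.0, 1.5), (-1.0, 0.5), "G3"),  # down in RR, up in SP
        ((-2.0, -1.5), (-1.0, -0.5), "G4"),
        ((2.0, 1.5), (-1.0, 0.5), "G5"),   # discordant between cell types
        ((0.0, 1.5), (1.0, 0.5), "G5"),    # exact zero -> no direction
    ])
    def test_direction_patterns(self, cd4, cd8, expected):
        t_stats = self._tstats({
            "CD4": {"HC-RR": cd4[0], "RR-SP": cd4[1]},
            "CD8": {"HC-RR": cd8[0], "RR-SP": cd8[1]}})
        labels = n.assign_expression_groups(t_stats, ["f"])
        assert labels.loc["f"] == expected
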