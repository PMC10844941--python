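"""Association engine: OLS panel fits, LRT, BH-FDR, influence, VIF, heterogeneity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from actigut.association import (
    EXPOSURES,
    FeatureAssociationModel,
    ModelSpec,
    bh_adjust,
    design_matrix,
    fit_joint_model,
    heterogeneity_test,
    lrt_screen,
    sensitivity_run,
    vif,
)
from actigut.errors import AlignmentError


def _toy_panel(rng, n=150, m=8, beta_mpa=0.0, outlier=False):
    """Small feature panel with numeric + categorical covariates."""
    idx = pd.Index([f"S{i:03d}" for i in range(n)], name="sample")
    exposures = pd.DataFrame(
        rng.standard_normal((n, 3)), index=idx, columns=list(EXPOSURES))
    cov = pd.DataFrame({
        "age": rng.normal(57, 4, n),
        "sex": rng.choice(["female", "male"], n),
        "smoking": rng.choice(["never", "former", "current"], n),
    }, index=idx)
    Y = rng.standard_normal((n, m))
    Y[:, 0] += beta_mpa * exposures["z_alr_MPA"].to_numpy()
    if outlier:
        Y[0, 1] += 30.0
        exposures.iloc[0, 1] += 8.0
    features = pd.DataFrame(Y, index=idx, columns=[f"f{j}" for j in range(m)])
    return features, exposures, cov


SPEC = ModelSpec(covariates=("age", "sex", "smoking"))


class TestOLSOracle:
    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        features, exposures, cov = _toy_panel(rng, beta_mpa=0.4)
        model = FeatureAssociationModel(features, exposures, cov, SPEC)
        res = model.fit(influence_screen=False, heterogeneity=False)

        X = model.X_full.to_numpy(dtype=float)
        for feat in ("f0", "f3"):
            ref = sm.OLS(features[feat].to_numpy(), X).fit()
            j = model.X_full.columns.get_loc("z_alr_MPA")
            assert res.table.loc[feat, "beta_MPA"] == pytest.approx(ref.params[j], rel=1e-10)
            assert res.table.loc[feat, "se_MPA"] == pytest.approx(ref.bse[j], rel=1e-10)
            assert res.table.loc[feat, "p_MPA"] == pytest.approx(ref.pvalues[j], rel=1e-8)

    def test_single_feature_entry_point(self, rng):
        import statsmodels.api as sm

        features, exposures, cov = _toy_panel(rng)
        X = pd.concat([design_matrix(cov, ["age", "sex"]), exposures], axis=1)
        fit = fit_joint_model(features["f0"], X)
        ref = sm.OLS(features["f0"].to_numpy(), X.to_numpy(dtype=float)).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-10)
        assert fit.llf == pytest.approx(ref.llf, rel=1e-10)
        assert np.allclose(fit.resid, ref.resid, atol=1e-10)

    def test_exact_linear_fit_residuals_zero(self, rng):
        features, exposures, cov = _toy_panel(rng, m=2)
        X = pd.concat([design_matrix(cov, ["age"]), exposures], axis=1)
        y = X.to_numpy(dtype=float) @ np.arange(1.0, X.shape[1] + 1)
        fit = fit_joint_model(y, X)
        assert np.abs(fit.resid).max() < 1e-8

    def test_rank_deficiency_reported(self, rng):
        features, exposures, cov = _toy_panel(rng)
        cov["dup"] = cov["age"]
        spec = ModelSpec(covariates=("age", "dup"))
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            FeatureAssociationModel(features, exposures, cov, spec).fit()

    def test_misaligned_index_rejected(self, rng):
        features, exposures, cov = _toy_panel(rng)
        with pytest.raises(AlignmentError):
            FeatureAssociationModel(features.iloc[:-1], exposures, cov, SPEC)


class TestLRT:
    def test_chisq_reference_value(self):
        # a statistic of 7.81 on 3 df sits at the 5% tail
        assert stats.chi2.sf(7.8147279, 3) == pytest.approx(0.05, abs=1e-6)

    def test_screen_null_features_uniform_p(self, rng):
        features, exposures, cov = _toy_panel(rng, n=400, m=300)
        out = lrt_screen(features, exposures, cov, SPEC)
        assert (out["lrt_stat"] >= 0).all()
        frac = (out["lrt_p"] < 0.05).mean()
        lo, hi = stats.binom.interval(0.999, 300, 0.05)
        assert lo / 300 <= frac <= hi / 300

    def test_planted_effect_detected(self, rng):
        features, exposures, cov = _toy_panel(rng, n=400, beta_mpa=0.5)
        out = lrt_screen(features, exposures, cov, SPEC)
        assert out.loc["f0", "lrt_p"] < 1e-10

    def test_p_monotone_in_statistic(self, rng):
        features, exposures, cov = _toy_panel(rng, n=200, m=50)
        out = lrt_screen(features, exposures, cov, SPEC).sort_values("lrt_stat")
        assert out["lrt_p"].is_monotonic_decreasing


class TestBH:
    def test_hand_computed_stepup(self):
        q, flags = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)
        assert flags.all()

    def test_edge_cases(self):
        q, _ = bh_adjust(np.array([1.0, 1.0, 1.0]))
        assert np.allclose(q, 1.0)
        q, _ = bh_adjust(np.array([0.037]))
        assert q[0] == pytest.approx(0.037)

    def test_matches_statsmodels_and_classical_rejection_set(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200) ** 2
        q, flags = bh_adjust(p, 0.05)
        ref_flags, ref_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(q, ref_q, atol=1e-12)
        assert np.array_equal(flags, ref_flags)

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=100)
        q, _ = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_nan_handling(self):
        q, flags = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and not flags[1]
        with pytest.raises(ValueError):
            bh_adjust(np.array([1.5]))


class TestVIF:
    def test_orthogonal_predictors_unity(self):
        n = 64
        X = pd.DataFrame({"Intercept": 1.0,
                          "a": np.tile([1, -1], n // 2),
                          "b": np.repeat([1, -1], n // 2)})
        out = vif(X, ["a", "b"])
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_correlated_pair_closed_form(self):
        # two standardized predictors with r = 0.6 -> VIF = 1/(1-0.36)
        rng = np.random.default_rng(5)
        z = rng.standard_normal((4000, 2))
        a = z[:, 0]
        b = 0.6 * z[:, 0] + np.sqrt(1 - 0.36) * z[:, 1]
        # orthogonalize empirically to hit r=0.6 exactly
        a = (a - a.mean()) / a.std()
        b = b - np.polyval(np.polyfit(a, b, 1), a)
        b = 0.6 * a + np.sqrt(1 - 0.36) * (b - b.mean()) / b.std()
        X = pd.DataFrame({"Intercept": np.ones(len(a)), "a": a, "b": b})
        out = vif(X, ["a", "b"])
        assert out["a"] == pytest.approx(1.5625, abs=1e-9)

    def test_duplicated_column_infinite(self, rng):
        x = rng.standard_normal(50)
        X = pd.DataFrame({"Intercept": 1.0, "a": x, "b": x})
        assert np.isinf(vif(X, ["a"]).iloc[0])


class TestDfbetasAndInfluence:
    def test_dfbetas_match_leave_one_out_refit(self, rng):
        # closed form vs explicit refits, on several random datasets
        for _ in range(10):
            features, exposures, cov = _toy_panel(rng, n=60, m=3)
            model = FeatureAssociationModel(features, exposures, cov, SPEC)
            Y = model.features.to_numpy(dtype=float)
            Xf = model.X_full.to_numpy(dtype=float)
            from actigut.association import _qr_fit
            B, E, rss, XtX_inv = _qr_fit(Xf, Y)
            n, p = Xf.shape
            sigma2 = rss / (n - p)
            exp_idx = [model.X_full.columns.get_loc(e) for e in EXPOSURES]
            dfb = model._dfbetas(Xf, Y, B, E, XtX_inv, exp_idx, sigma2)
            for i in (0, 17, 41):
                keep = np.ones(n, dtype=bool)
                keep[i] = False
                Bi, Ei, rssi, XtX_inv_i = _qr_fit(Xf[keep], Y[keep])
                s2_i = rssi / (n - 1 - p)
                for k, j in enumerate(exp_idx):
                    manual = (B[j] - Bi[j]) / np.sqrt(s2_i * XtX_inv[j, j])
                    assert np.allclose(dfb[i, k], manual, atol=1e-8)

    def test_outlier_driven_association_discarded(self, rng):
        features, exposures, cov = _toy_panel(rng, n=120, outlier=True)
        res = FeatureAssociationModel(features, exposures, cov, SPEC).fit()
        row = res.table.loc["f1"]
        assert row["influence_discarded"]
        assert not row["significant"]
        assert row["influence_obs"] == "S000"

    def test_strong_planted_effect_survives_screen(self, rng):
        features, exposures, cov = _toy_panel(rng, n=500, beta_mpa=0.6)
        res = FeatureAssociationModel(features, exposures, cov, SPEC).fit()
        row = res.table.loc["f0"]
        assert row["significant"] and not row["influence_discarded"]

    def test_zero_residual_observation_has_zero_dfbeta(self, rng):
        # construct noise orthogonal to the design AND zero at observation 0:
        # OLS then reproduces the true coefficients with residual e, e_0 = 0,
        # so deleting observation 0 changes nothing
        features, exposures, cov = _toy_panel(rng, n=80, m=1)
        model = FeatureAssociationModel(features, exposures, cov, SPEC)
        X = model.X_full.to_numpy(dtype=float)
        n = X.shape[0]
        basis = np.column_stack([X, np.eye(n)[:, 0]])
        e = rng.standard_normal(n)
        e -= basis @ np.linalg.lstsq(basis, e, rcond=None)[0]
        y = (X @ np.ones(X.shape[1]) + e).reshape(-1, 1)
        from actigut.association import _qr_fit
        B, E, rss, XtX_inv = _qr_fit(X, y)
        exp_idx = [model.X_full.columns.get_loc(c) for c in EXPOSURES]
        dfb = model._dfbetas(X, y, B, E, XtX_inv, exp_idx, rss / (n - X.shape[1]))
        assert np.abs(dfb[0]).max() < 1e-8
        assert np.abs(dfb[1:]).max() > 1e-6  # other observations do contribute


class TestHeterogeneity:
    def test_equal_coefficients_statistic_zero(self):
        stat, p = heterogeneity_test(0.25, 0.25, 0.01, df_resid=100)
        assert stat == 0.0 and p == 1.0

    def test_f_and_chi2_forms(self):
        stat_f, p_f = heterogeneity_test(0.3, 0.1, 0.005, df_resid=10_000)
        stat_c, p_c = heterogeneity_test(0.3, 0.1, 0.005, df_resid=10_000, form="chi2")
        assert stat_f == stat_c == pytest.approx(8.0)
        assert p_f == pytest.approx(p_c, rel=1e-2)  # F -> chi2 as df grows

    def test_size_under_equal_effects(self, rng):
        # many features sharing beta_MPA = beta_VPA: rejection ~ alpha
        n, m = 250, 400
        features, exposures, cov = _toy_panel(rng, n=n, m=m)
        common = exposures["z_alr_MPA"] + exposures["z_alr_VPA"]
        Y = 0.5 * common.to_numpy()[:, None] + rng.standard_normal((n, m))
        features = pd.DataFrame(Y, index=features.index, columns=features.columns)
        model = FeatureAssociationModel(features, exposures, cov, SPEC)
        res = model.fit(influence_screen=False, heterogeneity=False)
        # compute the contrast for every feature regardless of significance
        Xf = model.X_full.to_numpy(dtype=float)
        from actigut.association import _qr_fit
        B, E, rss, XtX_inv = _qr_fit(Xf, model.features.to_numpy(dtype=float))
        p_ = Xf.shape[1]
        j1 = model.X_full.columns.get_loc("z_alr_MPA")
        j2 = model.X_full.columns.get_loc("z_alr_VPA")
        var_diff = (XtX_inv[j1, j1] + XtX_inv[j2, j2] - 2 * XtX_inv[j1, j2]) * rss / (n - p_)
        stat, pv = heterogeneity_test(B[j1], B[j2], var_diff, n - p_)
        rate = (pv < 0.05).mean()
        lo, hi = stats.binom.interval(0.999, m, 0.05)
        assert lo / m <= rate <= hi / m

    def test_power_with_unequal_effects(self, rng):
        features, exposures, cov = _toy_panel(rng, n=2000, m=4)
        y = 0.4 * exposures["z_alr_MPA"].to_numpy() + rng.standard_normal(2000)
        features["f0"] = y
        res = FeatureAssociationModel(features, exposures, cov, SPEC).fit()
        assert res.table.loc["f0", "het_p"] < 0.05


class TestStandardizationInvariance:
    def test_doubling_alr_variance_leaves_t_statistics_unchanged(self, rng):
        features, exposures, cov = _toy_panel(rng, n=300, beta_mpa=0.3)
        res1 = FeatureAssociationModel(features, exposures, cov, SPEC).fit(
            influence_screen=False, heterogeneity=False)
        # doubling raw alr variance then re-standardizing is a no-op on z
        raw = exposures * 2.0
        rez = (raw - raw.mean()) / raw.std(ddof=1)
        rez.columns = exposures.columns
        res2 = FeatureAssociationModel(features, rez, cov, SPEC).fit(
            influence_screen=False, heterogeneity=False)
        t1 = res1.table["beta_MPA"] / res1.table["se_MPA"]
        t2 = res2.table["beta_MPA"] / res2.table["se_MPA"]
        assert np.allclose(t1, t2, atol=1e-8)


class TestSensitivity:
    @staticmethod
    def _plant(features, exposures, rng, k=4):
        for j, col in enumerate(features.columns[:k]):
            features[col] = (0.4 + 0.1 * j) * exposures["z_alr_MPA"].to_numpy() \
                + rng.standard_normal(len(features))
        return features

    def test_identity_variant_reproduces_base(self, rng):
        features, exposures, cov = _toy_panel(rng, n=300)
        features = self._plant(features, exposures, rng)
        base = FeatureAssociationModel(features, exposures, cov, SPEC).fit()
        rep = sensitivity_run(base, {"same": SPEC}, features, exposures, cov)
        assert rep.loc["same", "n_remaining_significant"] == len(base.significant)
        assert rep.loc["same", "spearman_MPA"] == pytest.approx(1.0)

    def test_noise_covariate_changes_little(self, rng):
        features, exposures, cov = _toy_panel(rng, n=400)
        features = self._plant(features, exposures, rng)
        cov["noise"] = rng.standard_normal(len(cov))
        variant = ModelSpec(name="plus_noise", covariates=("age", "sex", "smoking", "noise"))
        base = FeatureAssociationModel(features, exposures, cov, SPEC).fit()
        rep = sensitivity_run(base, {"plus_noise": variant}, features, exposures, cov)
        assert rep.loc["plus_noise", "n_remaining_significant"] == len(base.significant)
        assert rep.loc["plus_noise", "spearman_MPA"] > 0.95

    def test_complete_case_exclusion_counted(self, rng):
        features, exposures, cov = _toy_panel(rng, n=100)
        cov.loc[cov.index[:7], "age"] = np.nan
        model = FeatureAssociationModel(features, exposures, cov, SPEC)
        assert model.n_excluded_incomplete == 7
        assert len(model.features) == 93
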