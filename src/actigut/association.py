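"""Per-feature association engine for time-use exposures and microbiome features.

Each clr-transformed feature (species or functional module) is regressed,
one at a time, on the three standardized alr exposures (SED, MPA, VPA)
entered jointly, plus the covariates of a :class:`ModelSpec`.  A
likelihood-ratio test (3 df) against the covariates-only model screens
features, Benjamini-Hochberg controls the FDR, a dfbeta-based influence
screen discards associations driven by a single observation, and a Wald
contrast tests heterogeneity of the MPA and VPA coefficients.

Because thousands of features share a single design matrix, the engine
fits all of them at once via multi-response least squares (one QR
factorisation); this is algebraically identical to per-feature OLS.

Usage::

    model = FeatureAssociationModel(features, exposures, covariates, spec)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InsufficientDataError

__all__ = [
    "ModelSpec",
    "FeatureAssociationModel",
    "AssociationResults",
    "OLSFit",
    "fit_joint_model",
    "lrt_screen",
    "heterogeneity_test",
    "bh_adjust",
    "vif",
    "design_matrix",
    "sensitivity_run",
]

EXPOSURES = ("z_alr_SED", "z_alr_MPA", "z_alr_VPA")

#: covariates of the main adjustment set (confounders + technical variation)
MAIN_COVARIATES = [
    "age", "sex", "alcohol", "smoking", "education", "country_of_birth",
    "site", "month_of_wear", "whole_grain", "fruit_veg", "protein",
    "energy_intake", "wear_minutes", "pct_weekend_wear", "dna_plate",
]
ADIPOSITY_COVARIATES = MAIN_COVARIATES + ["bmi", "whr"]
MEDICATION_COVARIATES = MAIN_COVARIATES + ["ppi_use", "medication_use"]


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates to adjust for and which samples to keep.

    ``subset`` is an optional pandas query string evaluated on the
    covariate table (e.g. ``"antibiotics_3mo == 0"``).  The three
    exposures are always entered jointly and are not configurable.
    """

    name: str = "main"
    covariates: tuple[str, ...] = tuple(MAIN_COVARIATES)
    subset: str | None = None
    heterogeneity_form: str = "f"  # "f" (1, n-p df) or "chi2"
    lrt_reference: str = "f"  # "f": exact finite-sample null; "chisq": asymptotic
    fdr_threshold: float = 0.05

    @classmethod
    def main(cls) -> "ModelSpec":
        return cls()

    @classmethod
    def adiposity(cls) -> "ModelSpec":
        return cls(name="adiposity", covariates=tuple(ADIPOSITY_COVARIATES))

    @classmethod
    def medication_sensitivity(cls) -> "ModelSpec":
        return cls(name="medication", covariates=tuple(MEDICATION_COVARIATES))

    @classmethod
    def antibiotic_sensitivity(cls) -> "ModelSpec":
        return cls(name="no_antibiotics", subset="antibiotics_3mo == 0")


def design_matrix(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Expand the named columns into a numeric design matrix with intercept.

    Categorical (object/category/bool) columns get reference-level dummy
    coding; numeric columns pass through unchanged.
    """
    parts = [pd.Series(1.0, index=df.index, name="Intercept")]
    for col in columns:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float))
    return pd.concat(parts, axis=1)


def bh_adjust(p: np.ndarray | pd.Series, q_threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags.

    NaN p-values propagate to NaN q-values and count neither toward m nor
    toward any rejection.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        qq = np.empty(m)
        qq[order] = np.minimum(qv, 1.0)
        q[ok] = qq
    return q, q < q_threshold


def vif(X: pd.DataFrame, columns: list[str] | None = None) -> pd.Series:
    """Variance inflation factors 1/(1-R^2_j) for columns of a design matrix.

    Each requested column is regressed on all the *other* columns of ``X``
    (the intercept included).  Perfect collinearity yields ``inf``.
    """
    cols = columns if columns is not None else [c for c in X.columns if c != "Intercept"]
    mat = X.to_numpy(dtype=float)
    out = {}
    for name in cols:
        j = X.columns.get_loc(name)
        y = mat[:, j]
        others = np.delete(mat, j, axis=1)
        beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = ((y - y.mean()) ** 2).sum()
        rss = (resid**2).sum()
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def _qr_fit(X: np.ndarray, Y: np.ndarray):
    """Least squares of every column of Y on X via one QR factorisation.

    Returns (betas p x m, residuals n x m, rss m, XtX_inv p x p).
    """
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if np.any(diag < 1e-10 * diag.max()):
        bad = np.flatnonzero(diag < 1e-10 * diag.max())
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear column indices: {bad.tolist()}")
    B = np.linalg.solve(R, Q.T @ Y)
    E = Y - X @ B
    rss = (E**2).sum(axis=0)
    Rinv = np.linalg.solve(R, np.eye(R.shape[0]))
    XtX_inv = Rinv @ Rinv.T
    return B, E, rss, XtX_inv


def _gauss_loglik(rss: np.ndarray, n: int) -> np.ndarray:
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


def _lrt_pvalue(lrt, n: int, p: int, df_lrt: int, reference: str = "f"):
    """p-value of the Gaussian LRT statistic ``n ln(RSS_red/RSS_full)``.

    With Gaussian errors the statistic is an exact monotone function of
    the F(df_lrt, n-p) statistic, so ``reference="f"`` gives the exact
    finite-sample null (the default; identical feature ordering, better
    small-sample calibration); ``"chisq"`` uses the usual asymptotic
    df_lrt-df chi-square upper tail.
    """
    if reference == "chisq":
        return stats.chi2.sf(lrt, df_lrt)
    if reference != "f":
        raise ValueError("lrt_reference must be 'f' or 'chisq'")
    fstat = np.expm1(np.asarray(lrt, dtype=float) / n) * (n - p) / df_lrt
    return stats.f.sf(fstat, df_lrt, n - p)


@dataclass(frozen=True)
class OLSFit:
    """A single-response least-squares fit (Gaussian likelihood)."""

    params: pd.Series
    bse: pd.Series
    resid: np.ndarray
    rss: float
    llf: float
    df_resid: int
    cov_unit: np.ndarray  # (X'X)^-1; multiply by sigma2 for the coef covariance


def fit_joint_model(y: pd.Series | np.ndarray, X: pd.DataFrame) -> OLSFit:
    """OLS of one feature on a ready-made design matrix (intercept included).

    A convenience single-feature entry point; the panel engine in
    :class:`FeatureAssociationModel` is the vectorised equivalent.
    """
    Xm = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float).reshape(-1, 1)
    n, p = Xm.shape
    if n <= p:
        raise InsufficientDataError(f"n={n} <= p={p}")
    B, E, rss, XtX_inv = _qr_fit(Xm, yv)
    sigma2 = float(rss[0]) / (n - p)
    return OLSFit(
        params=pd.Series(B[:, 0], index=X.columns),
        bse=pd.Series(np.sqrt(np.diag(XtX_inv) * sigma2), index=X.columns),
        resid=E[:, 0],
        rss=float(rss[0]),
        llf=float(_gauss_loglik(rss, n)[0]),
        df_resid=n - p,
        cov_unit=XtX_inv,
    )


def lrt_screen(
    features: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Per-feature 3-df likelihood-ratio test of the joint exposures.

    Compares the exposures+covariates model with the covariates-only model
    on identical samples; returns ``lrt_stat`` and ``lrt_p`` per feature.
    """
    model = FeatureAssociationModel(features, exposures, covariates, spec)
    res = model.fit(influence_screen=False, heterogeneity=False)
    return res.table[["lrt_stat", "lrt_p"]]


def heterogeneity_test(
    beta_mpa: float | np.ndarray,
    beta_vpa: float | np.ndarray,
    var_diff: float | np.ndarray,
    df_resid: int,
    form: str = "f",
):
    """Wald contrast of H0: beta_MPA = beta_VPA.

    ``var_diff`` is Var(b_MPA) + Var(b_VPA) - 2 Cov(b_MPA, b_VPA).  With
    ``form="f"`` the statistic is referred to F(1, df_resid) (matching the
    usual linear-hypothesis implementation); ``"chi2"`` uses the 1-df
    chi-square reference.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (np.asarray(beta_mpa) - np.asarray(beta_vpa)) ** 2 / np.asarray(var_diff)
    if form == "f":
        p = stats.f.sf(stat, 1, df_resid)
    elif form == "chi2":
        p = stats.chi2.sf(stat, 1)
    else:
        raise ValueError("form must be 'f' or 'chi2'")
    return stat, p


class FeatureAssociationModel:
    """Joint-exposure linear model over a panel of clr features.

    Parameters
    ----------
    features : samples x features DataFrame of clr-transformed abundances.
    exposures : DataFrame with columns ``z_alr_SED``, ``z_alr_MPA``,
        ``z_alr_VPA`` (standardized alr coordinates).
    covariates : DataFrame holding every column named in ``spec``.
    spec : the adjustment set / subset rule; defaults to the main model.

    All three tables must share their sample index.  Complete-case
    filtering happens once here, so the full and covariates-only fits see
    identical samples.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        exposures: pd.DataFrame,
        covariates: pd.DataFrame,
        spec: ModelSpec | None = None,
    ):
        self.spec = spec or ModelSpec.main()
        if not features.index.equals(exposures.index) or not features.index.equals(covariates.index):
            raise AlignmentError("features, exposures and covariates must share their sample index")
        missing = [c for c in self.spec.covariates if c not in covariates.columns]
        if missing:
            raise AlignmentError(f"covariate columns missing from table: {missing}")

        keep = pd.Series(True, index=features.index)
        if self.spec.subset:
            keep &= covariates.eval(self.spec.subset)
        cc = exposures[list(EXPOSURES)].notna().all(axis=1) & covariates[
            list(self.spec.covariates)
        ].notna().all(axis=1)
        keep &= cc
        self.n_excluded_incomplete = int((~cc).sum())

        feat_ok = features.notna().all(axis=0)
        self.dropped_features = list(features.columns[~feat_ok])

        self.features = features.loc[keep, feat_ok]
        self.exposures = exposures.loc[keep, list(EXPOSURES)]
        self.covariates = covariates.loc[keep]

        Xc = design_matrix(self.covariates, list(self.spec.covariates))
        Xe = self.exposures.astype(float)
        self.X_full = pd.concat([Xc, Xe], axis=1)
        self.X_reduced = Xc
        n, p = self.X_full.shape
        if n <= p:
            raise InsufficientDataError(f"n={n} samples <= p={p} design columns")

    # ------------------------------------------------------------------
    def fit(
        self,
        influence_screen: bool = True,
        heterogeneity: bool = True,
    ) -> "AssociationResults":
        """Fit all features; returns an :class:`AssociationResults`."""
        Y = self.features.to_numpy(dtype=float)
        Xf = self.X_full.to_numpy(dtype=float)
        Xr = self.X_reduced.to_numpy(dtype=float)
        n, p = Xf.shape
        m = Y.shape[1]

        B, E, rss_full, XtX_inv = _qr_fit(Xf, Y)
        _, _, rss_red, _ = _qr_fit(Xr, Y)

        df_lrt = Xf.shape[1] - Xr.shape[1]
        with np.errstate(divide="ignore"):
            lrt = n * np.log(rss_red / rss_full)
        lrt = np.maximum(lrt, 0.0)
        lrt_p = _lrt_pvalue(lrt, n, p, df_lrt, self.spec.lrt_reference)

        sigma2 = rss_full / (n - p)
        exp_idx = [self.X_full.columns.get_loc(e) for e in EXPOSURES]
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # p x m
        tvals = B / se
        coef_p = 2 * stats.t.sf(np.abs(tvals), n - p)

        q_lrt, sig = bh_adjust(lrt_p, self.spec.fdr_threshold)

        table = pd.DataFrame(index=self.features.columns)
        for label, j in zip(("SED", "MPA", "VPA"), exp_idx):
            table[f"beta_{label}"] = B[j]
            table[f"se_{label}"] = se[j]
            table[f"p_{label}"] = coef_p[j]
        table["lrt_stat"] = lrt
        table["lrt_p"] = lrt_p
        table["q"] = q_lrt
        table["significant"] = sig

        # per-coefficient BH across features, one family per exposure
        for label in ("SED", "MPA", "VPA"):
            table[f"q_{label}"], _ = bh_adjust(table[f"p_{label}"].to_numpy(),
                                               self.spec.fdr_threshold)

        vifs = vif(self.X_full, list(EXPOSURES))

        if influence_screen:
            self._influence(table, Xf, Xr, Y, B, E, XtX_inv, exp_idx, sigma2)
        else:
            table["influence_discarded"] = False
            table["influence_obs"] = None

        if heterogeneity:
            self._heterogeneity(table, XtX_inv, sigma2, exp_idx, n, p, B)

        return AssociationResults(model=self, table=table, vifs=vifs,
                                  n_samples=n, n_params=p)

    # ------------------------------------------------------------------
    def _dfbetas(self, Xf, Y, B, E, XtX_inv, exp_idx, sigma2):
        """Standardized dfbetas for the exposure coefficients.

        Closed form: dfbeta_ij = (XtX^-1 x_i)_j e_i / (1 - h_i),
        standardized by s_(i) * sqrt((XtX^-1)_jj) with the leave-one-out
        residual variance s_(i)^2.  Shape (n, 3, m).
        """
        n, p = Xf.shape
        C = XtX_inv @ Xf.T            # p x n
        h = np.einsum("ij,ji->i", Xf, C)
        one_m_h = 1.0 - h
        dof = n - p
        # s2_loo: (n, m)
        s2_loo = (dof * sigma2[None, :] - (E**2) / one_m_h[:, None]) / (dof - 1)
        s2_loo = np.maximum(s2_loo, 1e-300)
        raw = C[exp_idx].T[:, :, None] * (E / one_m_h[:, None])[:, None, :]  # n x 3 x m
        return raw / np.sqrt(s2_loo)[:, None, :] / np.sqrt(np.diag(XtX_inv)[exp_idx])[None, :, None]

    def _influence(self, table, Xf, Xr, Y, B, E, XtX_inv, exp_idx, sigma2):
        """Discard significant associations driven by a single observation."""
        dfb = self._dfbetas(Xf, Y, B, E, XtX_inv, exp_idx, sigma2)  # n x 3 x m
        worst = np.abs(dfb).max(axis=1).argmax(axis=0)  # per feature: obs index
        table["influence_obs"] = [self.features.index[i] for i in worst]
        discarded = np.zeros(len(table), dtype=bool)
        n = Xf.shape[0]
        df_lrt = Xf.shape[1] - Xr.shape[1]
        sig_idx = np.flatnonzero(table["significant"].to_numpy())
        for f in sig_idx:
            i = worst[f]
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            y = Y[keep, f]
            bf, *_ = np.linalg.lstsq(Xf[keep], y, rcond=None)
            br, *_ = np.linalg.lstsq(Xr[keep], y, rcond=None)
            rss_f = ((y - Xf[keep] @ bf) ** 2).sum()
            rss_r = ((y - Xr[keep] @ br) ** 2).sum()
            stat = max((n - 1) * np.log(rss_r / rss_f), 0.0)
            p_refit = float(_lrt_pvalue(stat, n - 1, Xf.shape[1], df_lrt,
                                        self.spec.lrt_reference))
            if p_refit >= 0.05:
                discarded[f] = True
        table["influence_discarded"] = discarded
        table.loc[table["influence_discarded"], "significant"] = False

    def _heterogeneity(self, table, XtX_inv, sigma2, exp_idx, n, p, B):
        """Wald contrast of the MPA and VPA coefficients (H0: equal).

        Tested only for features whose MPA or VPA coefficient is
        individually significant (per-exposure BH q < threshold) among the
        screened set; BH is then applied across tested features.
        """
        j_mpa, j_vpa = exp_idx[1], exp_idx[2]
        var_unit = XtX_inv[j_mpa, j_mpa] + XtX_inv[j_vpa, j_vpa] - 2 * XtX_inv[j_mpa, j_vpa]
        stat, pvals = heterogeneity_test(
            B[j_mpa], B[j_vpa], var_unit * sigma2, n - p,
            form=self.spec.heterogeneity_form)
        eligible = table["significant"].to_numpy() & (
            (table["q_MPA"] < self.spec.fdr_threshold).to_numpy()
            | (table["q_VPA"] < self.spec.fdr_threshold).to_numpy()
        )
        table["het_stat"] = np.where(eligible, stat, np.nan)
        table["het_p"] = np.where(eligible, pvals, np.nan)
        table["het_q"], _ = bh_adjust(table["het_p"].to_numpy(), self.spec.fdr_threshold)


@dataclass
class AssociationResults:
    """Fitted per-feature association results.

    ``table`` has one row per feature with the three exposure coefficients
    and standard errors, the 3-df LRT statistic and p-value, BH q-values
    (``q`` across the LRT family, ``q_SED``/``q_MPA``/``q_VPA`` per
    exposure), influence-screen outcome and the MPA-vs-VPA heterogeneity
    contrast.
    """

    model: FeatureAssociationModel
    table: pd.DataFrame
    vifs: pd.Series
    n_samples: int
    n_params: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self, top: int = 10) -> str:
        t = self.table
        sig = t["significant"]
        lines = [
            f"Feature association results — {self.model.spec.name} model",
            f"  samples: {self.n_samples}   design columns: {self.n_params}",
            f"  features tested: {len(t)}   significant (q<{self.model.spec.fdr_threshold:g}): {int(sig.sum())}",
            f"  discarded by influence screen: {int(t['influence_discarded'].sum())}",
            f"  max VIF among exposures: {self.vifs.max():.3f} ({self.vifs.idxmax()})",
            "",
        ]
        show = t.loc[sig].nsmallest(top, "q") if sig.any() else t.nsmallest(top, "lrt_p")
        cols = ["beta_SED", "beta_MPA", "beta_VPA", "lrt_p", "q"]
        lines.append(show[cols].to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def sensitivity_run(
    base: AssociationResults,
    variants: dict[str, ModelSpec],
    features: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Re-fit the base run's significant features under variant specs.

    Returns one row per variant with counts remaining significant and
    Spearman correlations of the exposure coefficients against the base
    run (over the base-significant features).
    """
    sig_feats = base.significant.index
    rows = []
    for name, spec in variants.items():
        res = FeatureAssociationModel(features, exposures, covariates, spec).fit()
        common = sig_feats.intersection(res.table.index)
        row = {"variant": name, "n_base_significant": len(sig_feats),
               "n_remaining_significant": int(res.table.loc[common, "significant"].sum())}
        for label in ("SED", "MPA", "VPA"):
            a = base.table.loc[common, f"beta_{label}"]
            b = res.table.loc[common, f"beta_{label}"]
            rho = stats.spearmanr(a, b).statistic if len(common) > 1 else np.nan
            row[f"spearman_{label}"] = rho
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")
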