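"""Alpha-diversity regressions and partial distance-based redundancy analysis.

Partial dbRDA asks how much of the between-sample dissimilarity structure
(e.g. Bray-Curtis) the constraints (the three time-use exposures) explain
after the conditions (covariates) have been partialled out:

1. Gower double-centering of -D^2/2 and eigendecomposition give principal
   coordinates; axes with positive eigenvalues are kept (the inertia on
   negative axes of a non-Euclidean dissimilarity is dropped and
   reported).
2. Both the coordinates and the constraints are residualized on the
   conditions (with intercept).
3. Constrained inertia is the squared norm of the projection of the
   residualized coordinates onto the residualized constraints; adjusted
   R-squared uses the Ezekiel correction as the difference between the
   conditions+constraints and conditions-only adjustments.
4. Permutation p-values use the Freedman-Lane scheme: residuals of the
   coordinates on the conditions are permuted, re-residualized, and the
   pseudo-F recomputed; p = (#{F* >= F} + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import EXPOSURES, design_matrix, _qr_fit
from .errors import AlignmentError, DomainError

__all__ = ["PartialDBRDA", "OrdinationResults", "alpha_regression"]

EIG_TOL = 1e-9


def alpha_regression(
    alpha: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_columns: list[str],
) -> pd.DataFrame:
    """OLS of each alpha-diversity metric on the joint exposures + covariates.

    Returns a tidy table with one row per (metric, exposure): coefficient
    per SD of the alr exposure, SE, 95% CI and two-sided p-value.
    """
    if not alpha.index.equals(exposures.index) or not alpha.index.equals(covariates.index):
        raise AlignmentError("alpha metrics, exposures and covariates must share their index")
    X = pd.concat(
        [design_matrix(covariates, covariate_columns), exposures[list(EXPOSURES)].astype(float)],
        axis=1,
    )
    Xm = X.to_numpy(dtype=float)
    Y = alpha.to_numpy(dtype=float)
    n, p = Xm.shape
    B, E, rss, XtX_inv = _qr_fit(Xm, Y)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    tcrit = stats.t.ppf(0.975, n - p)
    rows = []
    for mi, metric in enumerate(alpha.columns):
        for label, name in zip(("SED", "MPA", "VPA"), EXPOSURES):
            j = X.columns.get_loc(name)
            b, s = B[j, mi], se[j, mi]
            pval = 2 * stats.t.sf(abs(b / s), n - p) if s > 0 else np.nan
            rows.append({"metric": metric, "exposure": label, "beta": b, "se": s,
                         "ci_low": b - tcrit * s, "ci_high": b + tcrit * s, "p": pval})
    return pd.DataFrame(rows)


def _orth(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    if M.size == 0:
        return np.zeros((M.shape[0], 0))
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    rank = int((s > s.max() * 1e-10).sum()) if s.size and s.max() > 0 else 0
    return U[:, :rank]


def _ezekiel(r2: float, n: int, df: int) -> float:
    if n - 1 - df <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - df)


@dataclass
class OrdinationResults:
    """Inertia decomposition and permutation inference of a partial dbRDA."""

    total_inertia: float
    conditioned_inertia: float
    constrained_inertia: float
    residual_inertia: float
    negative_inertia: float
    r2: float
    adj_r2: float
    pseudo_f: float
    p_value: float
    per_constraint: pd.DataFrame
    n_permutations: int
    seed: int | None
    n_samples: int

    def summary(self) -> str:
        lines = [
            "Partial distance-based redundancy analysis",
            f"  samples: {self.n_samples}   permutations: {self.n_permutations}",
            f"  total inertia (positive axes): {self.total_inertia:.6g}",
            f"  conditioned: {self.conditioned_inertia:.6g}   constrained: {self.constrained_inertia:.6g}   residual: {self.residual_inertia:.6g}",
            f"  discarded negative-axis inertia: {self.negative_inertia:.6g}",
            f"  joint semipartial R2: {self.r2:.6g}   adjusted R2: {self.adj_r2:.6g}",
            f"  pseudo-F: {self.pseudo_f:.4g}   permutation p: {self.p_value:.4g}",
            "",
            self.per_constraint.to_string(float_format=lambda v: f"{v:.5g}"),
        ]
        return "\n".join(lines)


class PartialDBRDA:
    """Partial dbRDA of a dissimilarity matrix on constraints given conditions.

    Parameters
    ----------
    distance : square symmetric DataFrame with zero diagonal.
    constraints : DataFrame of constraining variables (numeric), aligned
        with ``distance``.
    conditions : optional DataFrame of conditioning covariates; categorical
        columns are dummy-expanded.
    """

    def __init__(
        self,
        distance: pd.DataFrame,
        constraints: pd.DataFrame,
        conditions: pd.DataFrame | None = None,
    ):
        D = distance.to_numpy(dtype=float)
        if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
            raise DomainError("distance matrix must be square and symmetric")
        if not np.allclose(np.diag(D), 0, atol=1e-10):
            raise DomainError("distance matrix must have a zero diagonal")
        if not distance.index.equals(constraints.index):
            raise AlignmentError("constraints must be aligned with the distance matrix")
        if conditions is not None and not distance.index.equals(conditions.index):
            raise AlignmentError("conditions must be aligned with the distance matrix")
        self.D = D
        self.ids = distance.index
        self.constraints = constraints.astype(float)
        self.conditions = conditions

    def fit(
        self,
        n_perm: int = 999,
        seed: int | None = 0,
        permutation: str = "freedman_lane",
    ) -> OrdinationResults:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        n = self.D.shape[0]

        # principal-coordinate embedding
        A = -0.5 * self.D**2
        H = np.eye(n) - np.ones((n, n)) / n
        G = H @ A @ H
        w, V = np.linalg.eigh((G + G.T) / 2)
        scale = max(abs(w).max(), 1.0)
        pos = w > EIG_TOL * scale
        negative_inertia = float(-w[w < -EIG_TOL * scale].sum())
        Y = V[:, pos] * np.sqrt(w[pos])
        total = float(w[pos].sum())

        # conditions design (intercept always present; PCoA axes are centered)
        if self.conditions is not None and self.conditions.shape[1] > 0:
            Z = design_matrix(self.conditions, list(self.conditions.columns)).to_numpy(dtype=float)
        else:
            Z = np.ones((n, 1))
        Qz = _orth(Z)
        df_cond = Qz.shape[1] - 1  # intercept does not count

        Yr = Y - Qz @ (Qz.T @ Y)
        conditioned = total - float((Yr**2).sum())

        X = self.constraints.to_numpy(dtype=float)
        Xr = X - Qz @ (Qz.T @ X)
        # a constraint absorbed by the conditions leaves only rounding noise:
        # judge each residual column against its original scale
        xnorm = np.linalg.norm(X - X.mean(axis=0), axis=0)
        rnorm = np.linalg.norm(Xr, axis=0)
        absorbed = rnorm <= 1e-8 * np.maximum(xnorm, 1e-300)
        Qx = _orth(Xr[:, ~absorbed])
        q = Qx.shape[1]

        if q == 0:
            # constraints fully absorbed by the conditions: nothing to test
            constrained, pseudo_f = 0.0, 0.0
            residual = float((Yr**2).sum())
        else:
            proj = Qx.T @ Yr
            constrained = float((proj**2).sum())
            residual = float((Yr**2).sum()) - constrained
            df_res = n - 1 - df_cond - q
            pseudo_f = (constrained / q) / (residual / df_res)

        r2 = constrained / total
        r2_cond = conditioned / total
        adj_r2 = _ezekiel(r2_cond + r2, n, df_cond + q) - _ezekiel(r2_cond, n, df_cond)

        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]

        def _fstat(Qb: np.ndarray, Yin: np.ndarray, qb: int) -> float:
            c = float(((Qb.T @ Yin) ** 2).sum())
            r = float((Yin**2).sum()) - c
            return (c / qb) / (r / (n - 1 - df_cond - qb))

        if q == 0:
            p_value = 1.0
        else:
            exceed = 0
            for perm in perms:
                Yp = Yr[perm]
                if permutation == "freedman_lane":
                    Yp = Yp - Qz @ (Qz.T @ Yp)
                exceed += _fstat(Qx, Yp, q) >= pseudo_f
            p_value = (exceed + 1) / (n_perm + 1)

        # leave-one-in semipartial contribution per constraint
        rows = []
        for k, name in enumerate(self.constraints.columns):
            if absorbed[k]:
                rows.append({"constraint": name, "r2": 0.0, "adj_r2": 0.0,
                             "pseudo_f": 0.0, "p_value": 1.0})
                continue
            Qk = _orth(Xr[:, [k]])
            ck = float(((Qk.T @ Yr) ** 2).sum())
            rk = float((Yr**2).sum()) - ck
            fk = (ck / 1) / (rk / (n - 1 - df_cond - 1))
            exceed_k = 0
            for perm in perms:
                Yp = Yr[perm]
                if permutation == "freedman_lane":
                    Yp = Yp - Qz @ (Qz.T @ Yp)
                exceed_k += _fstat(Qk, Yp, 1) >= fk
            rows.append({
                "constraint": name,
                "r2": ck / total,
                "adj_r2": _ezekiel(r2_cond + ck / total, n, df_cond + 1) - _ezekiel(r2_cond, n, df_cond),
                "pseudo_f": fk,
                "p_value": (exceed_k + 1) / (n_perm + 1),
            })

        return OrdinationResults(
            total_inertia=total,
            conditioned_inertia=conditioned,
            constrained_inertia=constrained,
            residual_inertia=residual,
            negative_inertia=negative_inertia,
            r2=r2,
            adj_r2=adj_r2,
            pseudo_f=pseudo_f,
            p_value=p_value,
            per_constraint=pd.DataFrame(rows).set_index("constraint"),
            n_permutations=n_perm,
            seed=seed,
            n_samples=n,
        )
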