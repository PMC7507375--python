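"""Linear-mean GEE for pair-clustered data with robust (sandwich) variance.

Identity-link Gaussian generalized estimating equations for clusters of size
one or two, the design produced by double-entered twin pairs.  The working
correlation is exchangeable (single moment-estimated alpha pooled over
zygosities, geepack-style denominators) or independence; inference always
uses the cluster-robust sandwich covariance.

The solver is fully vectorized over clusters: for a 2x2 exchangeable block
R = [[1, a], [a, 1]], R^{-1} u = (u - a*swap(u)) / (1 - a^2), so one GEE
iteration is a handful of einsums.  This keeps large simulation studies
(thousands of refits) cheap on a single CPU.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .dataset import RegressionTable, TwinPairDataset, TwinDataError, drop_incomplete_pairs


class GEEError(RuntimeError):
    pass


class _ClusteredDesign:
    """Pre-sorted cluster layout: singles (size 1) and pairs (size 2)."""

    def __init__(self, y: np.ndarray, X: np.ndarray, clusters: np.ndarray):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        clusters = np.asarray(clusters)
        _, codes = np.unique(clusters, return_inverse=True)
        order = np.argsort(codes, kind="stable")
        codes = codes[order]
        self.y, self.X = y[order], X[order]
        sizes = np.bincount(codes)
        if sizes.max(initial=0) > 2:
            raise GEEError("clusters of size > 2 are not supported")
        self.n_clusters = sizes.size
        self.n_obs, self.p = self.X.shape
        # boundaries of each cluster in the sorted arrays
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        single = sizes == 1
        self.idx1 = starts[single]
        pair_starts = starts[~single]
        self.idxp = np.stack([pair_starts, pair_starts + 1], axis=1)  # (m2, 2)
        self.m2 = len(pair_starts)
        self.X1 = self.X[self.idx1]          # (m1, p)
        self.y1 = self.y[self.idx1]
        self.Xp = self.X[self.idxp]          # (m2, 2, p)
        self.yp = self.y[self.idxp]          # (m2, 2)

    # -- weighted normal equations --------------------------------------------
    def _rinv(self, u2: np.ndarray, alpha: float) -> np.ndarray:
        """Apply R^{-1} of the exchangeable 2x2 block along axis 1."""
        return (u2 - alpha * u2[:, ::-1]) / (1.0 - alpha * alpha)

    def solve_beta(self, alpha: float) -> np.ndarray:
        A, rhs = self._bread_rhs(alpha)
        return np.linalg.solve(A, rhs)

    def _bread_rhs(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        A = self.X1.T @ self.X1
        rhs = self.X1.T @ self.y1
        if self.m2:
            RiX = self._rinv(self.Xp, alpha)
            Riy = self._rinv(self.yp, alpha)
            A = A + np.einsum("mkp,mkq->pq", self.Xp, RiX)
            rhs = rhs + np.einsum("mkp,mk->p", self.Xp, Riy)
        return A, rhs

    def bread(self, alpha: float) -> np.ndarray:
        return self._bread_rhs(alpha)[0]

    # -- moments ---------------------------------------------------------------
    def residuals(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e1 = self.y1 - self.X1 @ beta
        ep = self.yp - self.Xp @ beta if self.m2 else np.zeros((0, 2))
        return e1, ep

    def scale_and_alpha(self, beta: np.ndarray) -> tuple[float, float]:
        """Moment estimates: scale with n-p denominator, alpha with m2-p."""
        e1, ep = self.residuals(beta)
        ssr = float(e1 @ e1 + (ep * ep).sum())
        phi = ssr / (self.n_obs - self.p)
        if self.m2 == 0 or phi <= 1e-300:
            return phi, 0.0
        cross = float((ep[:, 0] * ep[:, 1]).sum())
        denom = max(self.m2 - self.p, 1)
        alpha = cross / denom / phi
        return phi, float(np.clip(alpha, -0.95, 0.95))

    def scores(self, beta: np.ndarray, alpha: float) -> np.ndarray:
        """Per-cluster estimating-function contributions X_c' R^{-1} e_c."""
        e1, ep = self.residuals(beta)
        g1 = self.X1 * e1[:, None]
        if not self.m2:
            return g1
        Rie = self._rinv(ep, alpha)
        gp = np.einsum("mkp,mk->mp", self.Xp, Rie)
        return np.concatenate([g1, gp], axis=0)

    def augmented_system(
        self, beta: np.ndarray, alpha: float, phi: float, estimate_alpha: bool
    ) -> tuple[np.ndarray, np.ndarray]:
        """Joint estimating-function system for (beta, alpha, phi).

        Returns per-cluster contributions U (n_clusters x q) and the
        negative-Jacobian matrix A (q x q) of the stacked equations

            U_beta = X_c' R(alpha)^{-1} e_c
            U_alpha = e_c1 e_c2 - alpha phi          (pair clusters)
            U_phi  = e_c' e_c - n_c phi.

        When the mean model is misspecified at the cluster level (the
        outcome also depends on the partner's exposure), E[dU_beta/dalpha]
        does not vanish and the sampling noise of the moment alpha feeds
        into beta; the joint sandwich A^{-1} (sum U U') A^{-T} accounts for
        it, whereas the classical sandwich treats alpha as known.  With
        ``estimate_alpha=False`` the system reduces to U_beta alone.
        """
        p = self.p
        sc = self.scores(beta, alpha)
        if not estimate_alpha:
            return sc, self._bread_rhs(alpha)[0]
        e1, ep = self.residuals(beta)
        m1 = len(self.idx1)
        q = p + 2
        U = np.zeros((self.n_clusters, q))
        U[:, :p] = sc
        U[m1:, p] = ep[:, 0] * ep[:, 1] - alpha * phi
        U[:m1, p + 1] = e1 * e1 - phi
        U[m1:, p + 1] = (ep * ep).sum(axis=1) - 2 * phi

        A = np.zeros((q, q))
        A[:p, :p] = self.bread(alpha)
        if self.m2:
            # d(R^{-1} e)/dalpha = (2a e - (1 + a^2) swap(e)) / (1 - a^2)^2
            de = (2 * alpha * ep - (1 + alpha * alpha) * ep[:, ::-1]) / (
                (1 - alpha * alpha) ** 2
            )
            A[:p, p] = -np.einsum("mkp,mk->p", self.Xp, de)
            A[p, :p] = np.einsum("mkp,mk->p", self.Xp, ep[:, ::-1])
            A[p, p] = self.m2 * phi
            A[p, p + 1] = self.m2 * alpha
        A[p + 1, :p] = 2 * (
            self.X1.T @ e1 + np.einsum("mkp,mk->p", self.Xp, ep)
        )
        A[p + 1, p + 1] = self.n_obs
        return U, A


@dataclasses.dataclass
class GEEFit:
    """Result of a pair-clustered linear GEE fit.

    ``robust_cov`` is the cluster-level sandwich; when the working alpha is
    moment-estimated it comes from the joint (beta, alpha, phi) estimating
    system (see :meth:`_ClusteredDesign.augmented_system`), so alpha's
    sampling noise is propagated, and when alpha is fixed it is the
    classical B^{-1} M B^{-1} score sandwich.  ``naive_cov`` is the
    model-based scale * B^{-1}.
    """

    params: pd.Series
    robust_cov: pd.DataFrame
    naive_cov: pd.DataFrame
    working_alpha: float
    scale: float
    n_clusters: int
    n_obs: int
    converged: bool
    n_iter: int
    alpha_estimated: bool = True
    _design: _ClusteredDesign = dataclasses.field(repr=False, default=None)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.robust_cov)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": self.params.to_dict(),
            "robust_se": self.se.to_dict(),
            "p_values": self.pvalues.to_dict(),
            "working_alpha": self.working_alpha,
            "scale": self.scale,
            "n_clusters": self.n_clusters,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    deficient = diag <= tol
    if deficient.any():
        bad = [names[piv[i]] for i in np.nonzero(deficient)[0]]
        raise GEEError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_gee_arrays(
    y: np.ndarray,
    X: np.ndarray,
    clusters: np.ndarray,
    names: Sequence[str],
    working: str = "exchangeable",
    alpha_fixed: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GEEFit:
    """Fit the GEE on raw arrays.  ``names`` labels the columns of ``X``."""
    if working not in ("exchangeable", "independence"):
        raise GEEError(f"unknown working correlation: {working!r}")
    d = _ClusteredDesign(y, X, clusters)
    if d.n_clusters < 2:
        raise GEEError("need at least 2 clusters")
    _check_rank(d.X, list(names))

    if working == "independence":
        alpha_fixed = 0.0
    alpha = 0.0 if alpha_fixed is None else float(alpha_fixed)
    beta = d.solve_beta(alpha)
    converged, it = True, 0
    if working == "exchangeable" and alpha_fixed is None:
        converged = False
        trace = []
        for it in range(1, max_iter + 1):
            _, alpha = d.scale_and_alpha(beta)
            beta_new = d.solve_beta(alpha)
            delta = float(np.max(np.abs(beta_new - beta)))
            trace.append(delta)
            beta = beta_new
            if delta < tol:
                converged = True
                break
        if not converged:
            raise GEEError(
                f"GEE did not converge in {max_iter} iterations; "
                f"last |dbeta| trace tail: {trace[-5:]}"
            )
    phi, _ = d.scale_and_alpha(beta)

    estimate_alpha = (
        working == "exchangeable" and alpha_fixed is None and d.m2 > 0 and phi > 0
    )
    U, A = d.augmented_system(beta, alpha, phi, estimate_alpha)
    Ainv = np.linalg.inv(A)
    full = Ainv @ (U.T @ U) @ Ainv.T
    robust = full[: d.p, : d.p]
    robust = (robust + robust.T) / 2
    naive = phi * np.linalg.inv(d.bread(alpha))

    idx = pd.Index(names)
    return GEEFit(
        params=pd.Series(beta, index=idx),
        robust_cov=pd.DataFrame(robust, index=idx, columns=idx),
        naive_cov=pd.DataFrame(naive, index=idx, columns=idx),
        working_alpha=float(alpha),
        scale=float(phi),
        n_clusters=d.n_clusters,
        n_obs=d.n_obs,
        converged=converged,
        n_iter=it,
        alpha_estimated=estimate_alpha,
        _design=d,
    )


def fit_gee(
    table: RegressionTable,
    mean_model: Sequence[str],
    working: str = "exchangeable",
    alpha_fixed: float | None = None,
    **kwargs,
) -> GEEFit:
    """Fit ``y_self ~ intercept + mean_model`` clustered by pair.

    ``mean_model`` lists columns of the regression table, e.g.
    ``["x_self", "age", "height"]``; an intercept is always included.
    """
    y, X, clusters = table.design(mean_model)
    names = ["intercept", *mean_model]
    return fit_gee_arrays(
        y, X, clusters, names, working=working, alpha_fixed=alpha_fixed, **kwargs
    )


def compare_group_means(
    dataset: TwinPairDataset,
    trait: str,
    covariates: Sequence[str] = ("age", "height"),
) -> dict:
    """MZ-vs-DZ comparison of a trait mean, adjusted for covariates.

    Fits trait ~ MZ-indicator + covariates by GEE clustered on pair and
    returns the adjusted difference (MZ minus DZ), its robust SE, the
    two-sided Wald p, and per-group raw mean/SD/n for descriptive tables.
    """
    ds, _ = drop_incomplete_pairs(dataset, [trait, *covariates])
    df = ds.data
    groups = set(df["zygosity"])
    if len(groups) < 2:
        raise TwinDataError("both MZ and DZ groups are required")
    mz = (df["zygosity"] == "MZ").to_numpy(float)
    X = np.column_stack(
        [np.ones(len(df)), mz] + [df[c].to_numpy(float) for c in covariates]
    )
    names = ["intercept", "MZ", *covariates]
    fit = fit_gee_arrays(
        df[trait].to_numpy(float), X, df["pair_id"].to_numpy(), names
    )
    out = {
        "trait": trait,
        "difference": float(fit.params["MZ"]),
        "se": float(fit.se["MZ"]),
        "p": float(fit.pvalues["MZ"]),
    }
    for z in ("DZ", "MZ"):
        vals = df.loc[df["zygosity"] == z, trait]
        out[f"mean_{z}"] = float(vals.mean())
        out[f"sd_{z}"] = float(vals.std(ddof=1))
        out[f"n_{z}"] = int(len(vals))
    return out
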