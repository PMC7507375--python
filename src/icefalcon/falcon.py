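"""The ICE FALCON three-model procedure and coefficient-change inference.

Inference about Causation through Examination of FAmiliaL CONfounding fits,
to double-entered twin pairs, three pair-clustered GEE models of a bone (or
any) outcome on an exposure:

    Model 1:  y_self ~ x_self   + covariates        -> beta_self
    Model 2:  y_self ~ x_cotwin + covariates        -> beta_cotwin
    Model 3:  y_self ~ x_self + x_cotwin + covariates
                                      -> beta_self_adj, beta_cotwin_adj

If the exposure causes the outcome, conditioning on the individual's own
exposure explains away the cross-pair cross-trait association: beta_cotwin
attenuates towards zero while beta_self is unchanged.  If instead familial
factors drive both traits, the cotwin's exposure keeps predicting the
outcome after adjustment.  The changes delta_self = beta_self -
beta_self_adj and delta_cotwin = beta_cotwin - beta_cotwin_adj are tested
formally: the three models' estimating functions are stacked and the joint
sandwich covariance built from cluster-level scores gives
Var(delta) = Var(b1) + Var(b3) - 2 Cov(b1, b3); a cluster bootstrap
(resampling pairs) is available as an alternative and as a cross-check.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .dataset import TwinPairDataset, build_regression_table, RegressionTable
from .gee import GEEError, GEEFit, fit_gee, fit_gee_arrays

CAUSATION = "consistent_with_causation"
CONFOUNDING = "consistent_with_familial_confounding"
MIXED = "mixed"
INCONCLUSIVE = "inconclusive"


@dataclasses.dataclass(frozen=True)
class CoefEstimate:
    estimate: float
    se: float
    p: float

    @classmethod
    def from_fit(cls, fit: GEEFit, term: str) -> "CoefEstimate":
        return cls(
            estimate=float(fit.params[term]),
            se=float(fit.se[term]),
            p=float(fit.pvalues[term]),
        )

    def as_dict(self) -> dict:
        return {"estimate": self.estimate, "se": self.se, "p": self.p}


@dataclasses.dataclass(frozen=True)
class DeltaInference:
    """Joint covariance of the stacked models plus the delta tests."""

    joint_cov: pd.DataFrame          # index: (model number, term)
    deltas: dict[str, CoefEstimate]
    method: str
    n_boot: int | None = None


@dataclasses.dataclass(frozen=True)
class IceFalconResult:
    exposure: str
    outcome: str
    beta_self: CoefEstimate
    beta_cotwin: CoefEstimate
    beta_self_adj: CoefEstimate
    beta_cotwin_adj: CoefEstimate
    delta_self: CoefEstimate
    delta_cotwin: CoefEstimate
    label: str
    n_pairs: int
    alpha: float
    method: str
    working_alphas: tuple[float, float, float] = (np.nan,) * 3

    def coefficients(self) -> dict[str, CoefEstimate]:
        return {
            "beta_self": self.beta_self,
            "beta_cotwin": self.beta_cotwin,
            "beta_self_adj": self.beta_self_adj,
            "beta_cotwin_adj": self.beta_cotwin_adj,
            "delta_self": self.delta_self,
            "delta_cotwin": self.delta_cotwin,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = {k: v.as_dict() for k, v in self.coefficients().items()}
        out = pd.DataFrame(rows).T
        out.index.name = "statistic"
        return out

    def to_dict(self) -> dict:
        d = {k: v.as_dict() for k, v in self.coefficients().items()}
        d.update(
            exposure=self.exposure, outcome=self.outcome, label=self.label,
            n_pairs=self.n_pairs, alpha=self.alpha, method=self.method,
        )
        return d


# ---------------------------------------------------------------------------


def _stacked_inference(
    fits: Sequence[GEEFit],
    contrasts: Sequence[tuple[str, tuple[int, str], tuple[int, str]]],
) -> DeltaInference:
    """Joint sandwich over stacked estimating functions of several models.

    All fits must come from the same rows/clusters in the same order, which
    holds when they are fitted from one regression table.
    """
    n_cl = {f.n_clusters for f in fits}
    if len(n_cl) != 1:
        raise GEEError("stacked models must share clusters")
    # Each model contributes its full (beta, alpha, phi) estimating system so
    # that working-correlation estimation noise propagates into the joint
    # covariance; cross-model dependence enters through the score cross
    # products of shared clusters.
    systems = [
        f._design.augmented_system(
            f.params.to_numpy(), f.working_alpha, f.scale, f.alpha_estimated
        )
        for f in fits
    ]
    G = np.hstack([U for U, _ in systems])
    A = linalg.block_diag(*[Am for _, Am in systems])
    Ainv = np.linalg.inv(A)
    cov = Ainv @ (G.T @ G) @ Ainv.T
    cov = (cov + cov.T) / 2
    labels = []
    for m, (f, (U, _)) in enumerate(zip(fits, systems)):
        terms = list(f.params.index)
        extra = ["_alpha", "_phi"] if U.shape[1] > len(terms) else []
        labels.extend((m + 1, t) for t in terms + extra)
    index = pd.MultiIndex.from_tuples(labels, names=["model", "term"])
    keep = [i for i, (_, t) in enumerate(labels) if not t.startswith("_")]
    joint = pd.DataFrame(cov, index=index, columns=index).iloc[keep, keep]

    deltas = {}
    for label, (mi, ti), (mj, tj) in contrasts:
        est = float(fits[mi].params[ti] - fits[mj].params[tj])
        ii, jj = (mi + 1, ti), (mj + 1, tj)
        var = float(joint.loc[ii, ii] + joint.loc[jj, jj] - 2 * joint.loc[ii, jj])
        deltas[label] = _wald(est, var)
    return DeltaInference(joint_cov=joint, deltas=deltas, method="stacked")


def _wald(est: float, var: float) -> CoefEstimate:
    # A self-comparison has exactly zero variance; report no evidence of change.
    if var <= 0 or (var < 1e-24 and abs(est) < 1e-12):
        return CoefEstimate(estimate=est, se=0.0, p=1.0)
    se = float(np.sqrt(var))
    return CoefEstimate(estimate=est, se=se, p=float(2 * stats.norm.sf(abs(est) / se)))


def _bootstrap_inference(
    table: RegressionTable,
    model_specs: Sequence[Sequence[str]],
    fits: Sequence[GEEFit],
    contrasts,
    n_boot: int,
    seed: int | None,
    working: str,
) -> DeltaInference:
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    # Pre-extract cluster blocks once: all clusters have exactly 2 rows.
    designs = []
    for spec in model_specs:
        y, X, clusters = table.design(spec)
        order = np.argsort(clusters, kind="stable")
        y, X, clusters = y[order], X[order], clusters[order]
        m = len(np.unique(clusters))
        designs.append((y.reshape(m, 2), X.reshape(m, 2, -1), m))
    m = designs[0][2]
    names = [["intercept", *spec] for spec in model_specs]

    draws = np.empty((n_boot, len(contrasts)))
    for bi in range(n_boot):
        take = rng.integers(0, m, size=m)
        new_clusters = np.repeat(np.arange(m), 2)
        betas = []
        for (yb, Xb, _), nm in zip(designs, names):
            fit = fit_gee_arrays(
                yb[take].ravel(),
                Xb[take].reshape(2 * m, -1),
                new_clusters,
                nm,
                working=working,
            )
            betas.append(fit.params)
        for ci, (_, (mi, ti), (mj, tj)) in enumerate(contrasts):
            draws[bi, ci] = betas[mi][ti] - betas[mj][tj]

    deltas = {}
    for ci, (label, (mi, ti), (mj, tj)) in enumerate(contrasts):
        est = float(fits[mi].params[ti] - fits[mj].params[tj])
        se = float(np.std(draws[:, ci], ddof=1))
        if se == 0.0 and abs(est) > 1e-12:
            raise GEEError(f"degenerate bootstrap variance for {label}")
        deltas[label] = _wald(est, se * se)
    # Keep the stacked joint covariance shape for downstream consumers.
    stacked = _stacked_inference(fits, contrasts)
    return DeltaInference(
        joint_cov=stacked.joint_cov, deltas=deltas, method="bootstrap", n_boot=n_boot
    )


def joint_delta_inference(
    table: RegressionTable,
    model_specs: Sequence[Sequence[str]],
    contrasts: Sequence[tuple[str, tuple[int, str], tuple[int, str]]],
    method: str = "stacked",
    n_boot: int = 1000,
    seed: int | None = None,
    working: str = "exchangeable",
) -> tuple[list[GEEFit], DeltaInference]:
    """Fit several mean models on one table and test coefficient contrasts.

    ``contrasts`` entries are ``(label, (model_index, term), (model_index,
    term))`` and are tested as differences of the two named coefficients.
    """
    fits = []
    for k, spec in enumerate(model_specs, start=1):
        try:
            fits.append(fit_gee(table, spec, working=working))
        except GEEError as err:
            raise GEEError(f"Model {k} ({' + '.join(spec)}): {err}") from err
    if method == "stacked":
        inference = _stacked_inference(fits, contrasts)
    elif method == "bootstrap":
        inference = _bootstrap_inference(
            table, model_specs, fits, contrasts, n_boot, seed, working
        )
    else:
        raise ValueError(f"unknown delta inference method: {method!r}")
    return fits, inference


# ---------------------------------------------------------------------------


def classify(
    beta_cotwin_adj_p: float,
    delta_self_p: float,
    delta_cotwin_p: float,
    alpha: float = 0.05,
) -> str:
    """Interpretation rule applied to the component tests at level alpha.

    A significant attenuation of the cross-pair association with the
    cotwin coefficient vanishing (and the self coefficient stable) is the
    causal signature; a persistent cross-pair association without a
    significant change is the familial-confounding signature; both signals
    at once is labelled mixed; anything else is inconclusive.
    """
    d_cotwin_sig = delta_cotwin_p < alpha
    adj_sig = beta_cotwin_adj_p < alpha
    d_self_sig = delta_self_p < alpha
    if d_cotwin_sig and adj_sig:
        return MIXED
    if d_cotwin_sig and not d_self_sig and not adj_sig:
        return CAUSATION
    if adj_sig and not d_cotwin_sig:
        return CONFOUNDING
    return INCONCLUSIVE


def classify_result(result: IceFalconResult, alpha: float | None = None) -> str:
    a = result.alpha if alpha is None else alpha
    return classify(
        result.beta_cotwin_adj.p, result.delta_self.p, result.delta_cotwin.p, a
    )


MODEL_CONTRASTS = (
    ("delta_self", (0, "x_self"), (2, "x_self")),
    ("delta_cotwin", (1, "x_cotwin"), (2, "x_cotwin")),
)


def _check_standardized(table: RegressionTable) -> None:
    for col in ("y_self", "x_self"):
        v = table.data[col].to_numpy(float)
        if abs(v.mean()) > 0.2 or not 0.7 < v.std(ddof=1) < 1.4:
            warnings.warn(
                f"{col} does not look standardized (mean {v.mean():.2f}, "
                f"sd {v.std(ddof=1):.2f}); coefficients will not be comparable "
                "across traits",
                stacklevel=3,
            )


def run_ice_falcon(
    dataset: TwinPairDataset,
    exposure: str,
    outcome: str,
    covariates: Sequence[str] = ("age", "height"),
    alpha: float = 0.05,
    method: str = "stacked",
    n_boot: int = 1000,
    seed: int | None = None,
    working: str = "exchangeable",
    check_standardized: bool = True,
) -> IceFalconResult:
    """Run the full three-model procedure for one exposure/outcome pair."""
    table = build_regression_table(dataset, outcome, exposure, covariates)
    if table.n_clusters < 10:
        raise ValueError(
            f"need >= 10 complete pairs, have {table.n_clusters}"
        )
    if check_standardized:
        _check_standardized(table)
    cov = list(covariates)
    specs = [["x_self", *cov], ["x_cotwin", *cov], ["x_self", "x_cotwin", *cov]]
    fits, inference = joint_delta_inference(
        table, specs, MODEL_CONTRASTS, method=method, n_boot=n_boot, seed=seed,
        working=working,
    )
    m1, m2, m3 = fits
    res = IceFalconResult(
        exposure=exposure,
        outcome=outcome,
        beta_self=CoefEstimate.from_fit(m1, "x_self"),
        beta_cotwin=CoefEstimate.from_fit(m2, "x_cotwin"),
        beta_self_adj=CoefEstimate.from_fit(m3, "x_self"),
        beta_cotwin_adj=CoefEstimate.from_fit(m3, "x_cotwin"),
        delta_self=inference.deltas["delta_self"],
        delta_cotwin=inference.deltas["delta_cotwin"],
        label="",
        n_pairs=table.n_clusters,
        alpha=alpha,
        method=inference.method,
        working_alphas=tuple(f.working_alpha for f in fits),
    )
    return dataclasses.replace(res, label=classify_result(res))
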