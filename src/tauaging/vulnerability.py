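"""Elastic-net ranking of gene-set activities predicting cellular vulnerability.

The response is the per-cluster abundance log2FC restricted to clusters
with significant decline; predictors are cluster-level mean activities of
each gene set (cells pooled over genotypes and ages), standardized to mean
0 / sd 1.  The elastic net minimizes

    (1/2n) * sum r_i^2 + lambda * (alpha * ||b||_1 + (1-alpha)/2 * ||b||_2^2)

by cyclic coordinate descent with an unpenalized intercept.  (alpha,
lambda) are tuned by repeated k-fold cross-validation on mean RMSE, and
predictors are ranked by coefficient magnitude.  At these sample sizes
(around eight clusters against >100 predictors) the fit is a ranking
device, not an inferential model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .activity import ActivityMatrix

log = logging.getLogger(__name__)

__all__ = [
    "VulnerabilityDesign",
    "ElasticNetModel",
    "build_design",
    "enet_fit",
    "tune",
    "rank_predictors",
    "activity_decline_correlation",
    "default_alpha_grid",
    "default_lambda_grid",
]


@dataclass
class VulnerabilityDesign:
    """Standardized cluster-level design matrix plus response."""

    X: pd.DataFrame  # clusters × predictors, standardized
    y: pd.Series  # abundance log2FC per cluster
    column_means: pd.Series
    column_sds: pd.Series


def build_design(abundance: pd.DataFrame, act: ActivityMatrix,
                 meta: pd.DataFrame, extras: pd.DataFrame | None = None,
                 padj_threshold: float = 0.05, direction: str = "decline",
                 min_clusters: int = 3, allow_small: bool = False
                 ) -> VulnerabilityDesign:
    """Assemble the design from abundance records and an activity matrix.

    ``direction`` "decline" keeps clusters with padj < threshold and
    log2FC < 0 (the primary analysis); "any" keeps all significantly
    changed clusters.  Predictor columns are pooled-cell cluster means of
    each set's activity, standardized with the population sd; constant
    columns are dropped with a warning.
    """
    sig = abundance["padj"] < padj_threshold
    if direction == "decline":
        sig &= abundance["log2FC"] < 0
    elif direction != "any":
        raise ValueError("direction must be 'decline' or 'any'")
    selected = abundance.index[sig]
    if len(selected) < min_clusters and not allow_small:
        raise ValueError(
            f"only {len(selected)} qualifying clusters (<{min_clusters}); "
            "model underdetermined — pass allow_small=True to override"
        )
    meta = meta.loc[act.cells]
    pooled = act.values.groupby(meta["cluster"]).mean()  # clusters × sets
    X = pooled.loc[selected]
    if extras is not None:
        X = X.join(extras.loc[selected])
    if X.isna().any().any():
        raise ValueError("missing predictor values in the design")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} constant predictor columns")
    X = (X.loc[:, keep] - mean[keep]) / sd[keep]
    return VulnerabilityDesign(
        X=X, y=abundance.loc[selected, "log2FC"],
        column_means=mean[keep], column_sds=sd[keep],
    )


@dataclass
class ElasticNetModel:
    alpha: float
    lam: float
    intercept: float
    coef: pd.Series  # on the standardized predictor scale
    converged: bool = True
    cv_rmse: float | None = None
    tuning_trace: pd.DataFrame | None = None

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xv = X.to_numpy() if hasattr(X, "to_numpy") else np.asarray(X)
        return self.intercept + Xv @ self.coef.to_numpy()


def _soft_threshold(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def _cd_solve(X: np.ndarray, y: np.ndarray, alpha: float, lam: float,
              beta0: np.ndarray | None = None, tol: float = 1e-7,
              max_sweeps: int = 100_000):
    """Cyclic coordinate descent on the elastic-net objective.

    Returns (intercept, beta, converged).  The intercept is profiled out by
    centering; columns need not be standardized.
    """
    n, p = X.shape
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    col_ss = (Xc ** 2).sum(axis=0) / n  # per-column mean square
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    r = yc - Xc @ beta
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    converged = False
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if col_ss[j] == 0.0:
                continue
            bj = beta[j]
            rho = (Xc[:, j] @ r) / n + col_ss[j] * bj
            new = _soft_threshold(rho, l1) / (col_ss[j] + l2)
            if new != bj:
                r -= Xc[:, j] * (new - bj)
                beta[j] = new
                max_delta = max(max_delta, abs(new - bj))
        if max_delta < tol:
            converged = True
            break
    intercept = ym - xm @ beta
    return intercept, beta, converged


def enet_fit(design: VulnerabilityDesign, alpha: float, lam: float,
             tol: float = 1e-7) -> ElasticNetModel:
    """Fit the elastic net at fixed (alpha, lambda)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X = design.X.to_numpy()
    y = design.y.to_numpy()
    b0, beta, conv = _cd_solve(X, y, alpha, lam, tol=tol)
    if not conv:
        log.warning("coordinate descent did not converge at alpha=%g lam=%g",
                    alpha, lam)
    return ElasticNetModel(alpha=alpha, lam=lam, intercept=float(b0),
                           coef=pd.Series(beta, index=design.X.columns),
                           converged=conv)


def lambda_max(design: VulnerabilityDesign, alpha: float) -> float:
    """Smallest lambda that zeroes all coefficients (for alpha > 0 paths)."""
    X = design.X.to_numpy()
    y = design.y.to_numpy()
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    z = np.abs(Xc.T @ yc) / n
    if z.size == 0:
        return 1.0
    return float(z.max() / max(alpha, 1e-3))


def default_alpha_grid(n: int = 11) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def default_lambda_grid(design: VulnerabilityDesign, n: int = 30,
                        ratio: float = 1e-4) -> np.ndarray:
    lmax = lambda_max(design, alpha=1.0)
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax * ratio, lmax, n)


def tune(design: VulnerabilityDesign, alpha_grid=None, lambda_grid=None,
         k: int = 3, repeats: int = 100, seed: int = 0) -> ElasticNetModel:
    """Repeated k-fold CV over the (alpha, lambda) grid; winner = lowest RMSE.

    Each repeat uses a fresh seeded fold split.  Ties break toward larger
    lambda, then larger alpha.  The winning pair is refit on all rows.
    """
    X = design.X.to_numpy()
    y = design.y.to_numpy()
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} folds exceed {n} rows")
    alphas = np.asarray(alpha_grid if alpha_grid is not None
                        else default_alpha_grid())
    lams = np.sort(np.asarray(lambda_grid if lambda_grid is not None
                              else default_lambda_grid(design)))[::-1]
    rng = np.random.default_rng(seed)
    sq_err = np.zeros((len(alphas), len(lams)))
    counts = np.zeros_like(sq_err)
    for _rep in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fold in folds:
            test = np.zeros(n, dtype=bool)
            test[fold] = True
            Xtr, ytr = X[~test], y[~test]
            Xte, yte = X[test], y[test]
            for ai, a in enumerate(alphas):
                beta = None
                for li, lam in enumerate(lams):  # warm start down the path
                    b0, beta, _ = _cd_solve(Xtr, ytr, a, lam, beta0=beta)
                    pred = b0 + Xte @ beta
                    sq_err[ai, li] += ((pred - yte) ** 2).sum()
                    counts[ai, li] += len(yte)
    rmse = np.sqrt(sq_err / counts)
    # lowest RMSE; ties -> larger lambda, then larger alpha
    best = min(
        ((rmse[ai, li], -lams[li], -alphas[ai], ai, li)
         for ai in range(len(alphas)) for li in range(len(lams))),
    )
    ai, li = best[3], best[4]
    model = enet_fit(design, float(alphas[ai]), float(lams[li]))
    model.cv_rmse = float(rmse[ai, li])
    trace = pd.DataFrame(rmse, index=pd.Index(alphas, name="alpha"),
                         columns=pd.Index(lams, name="lambda"))
    model.tuning_trace = trace
    return model


def rank_predictors(model: ElasticNetModel) -> pd.Series:
    """Non-zero coefficients sorted by magnitude, descending."""
    nz = model.coef[model.coef != 0.0]
    if nz.empty:
        warnings.warn("all coefficients are zero; empty ranklist")
        return nz
    return nz.reindex(nz.abs().sort_values(ascending=False).index)


def activity_decline_correlation(cluster_activity: pd.Series,
                                 abundance: pd.DataFrame,
                                 padj_threshold: float = 0.05,
                                 direction: str = "decline"):
    """Pearson correlation of a set's cluster activity with abundance log2FC.

    Restricted to significantly changed clusters (declining by default).
    Returns (r, p) from the two-sided t-test, or (nan, nan) on degenerate
    input.
    """
    sig = abundance["padj"] < padj_threshold
    if direction == "decline":
        sig &= abundance["log2FC"] < 0
    clusters = [c for c in abundance.index[sig] if c in cluster_activity.index]
    if len(clusters) < 3:
        raise ValueError("need at least 3 qualifying clusters")
    x = cluster_activity.loc[clusters].to_numpy(dtype=float)
    y = abundance.loc[clusters, "log2FC"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
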