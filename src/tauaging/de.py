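"""Two-part (hurdle) differential expression testing.

Each gene's ln-normalized expression is modelled in two parts: a logistic
regression on the detection indicator (count > 0), absorbing stochastic
dropout, and a Gaussian linear model on the expression level of detected
cells.  Group effects are tested by a likelihood-ratio test whose statistic
and degrees of freedom sum over both parts.  The cellular detection rate
(CDR) is always a covariate; age (in days) is added for the age-adjusted
tau contrast.  Significance within each cluster requires BH-adjusted
p < 0.05, |avg_log2FC| > 0.1 and detection in at least 10% of cells of one
group.

The level part is fit by unpenalized least squares with an ML variance on
detected cells only; no empirical-Bayes shrinkage of variances or logistic
priors is applied.  Perfect separation in the detection part is handled by
a small ridge (1e-6) on the logistic coefficients, and such fits are
flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "HurdleFit",
    "ContrastDesign",
    "fit_hurdle",
    "hurdle_lrt",
    "log2fc",
    "de_test",
    "overlap_statistic",
    "significant_gene_sets",
]

_LN2 = np.log(2.0)
_RIDGE = 1e-6
_SEPARATION_BOUND = 20.0


# ---------------------------------------------------------------------------
# batched fitting primitives (shared design matrix, many genes)
# ---------------------------------------------------------------------------

def _batch_logistic(X: np.ndarray, D: np.ndarray, ridge: float = _RIDGE,
                    max_iter: int = 60, tol: float = 1e-9):
    """Newton-Raphson logistic fits for many response vectors at once.

    X is n × p; D is n × G in {0,1}.  Returns (beta p × G, ll G, flagged G).
    A tiny ridge stabilizes separated fits; genes whose coefficients run to
    the separation bound are flagged.  Log-likelihoods are unpenalized.
    """
    n, p = X.shape
    G = D.shape[1]
    beta = np.zeros((p, G))
    # initialize intercept at logit of detection rate (first column assumed 1)
    rate = np.clip(D.mean(axis=0), 1e-6, 1 - 1e-6)
    beta[0] = np.log(rate / (1 - rate))
    active = np.arange(G)
    eye = ridge * np.eye(p)[None, :, :]
    for _ in range(max_iter):
        Da = D[:, active]
        ba = beta[:, active]
        eta = np.clip(X @ ba, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = X.T @ (Da - mu) - ridge * ba
        H = np.einsum("np,ng,nq->gpq", X, W, X) + eye
        delta = np.linalg.solve(H, grad.T[:, :, None])[:, :, 0].T
        step = np.clip(delta, -5.0, 5.0)
        beta[:, active] = ba + step
        moved = np.abs(step).max(axis=0) >= tol
        active = active[moved]
        if active.size == 0:
            break
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    ll = (D * np.log(mu) + (1 - D) * np.log(1 - mu)).sum(axis=0)
    flagged = np.abs(beta).max(axis=0) > _SEPARATION_BOUND
    return beta, ll, flagged


def _batch_gaussian(X: np.ndarray, Y: np.ndarray, W: np.ndarray):
    """Weighted (0/1) least-squares fits of each column of Y on X.

    W is the detection indicator; each gene's level model uses its detected
    cells only.  Returns (beta p × G, ll G, ok G, rss G, nd G) where ll is
    the Gaussian ML log-likelihood on the detected subset and ok marks
    genes with enough detected cells for a full-rank fit.
    """
    n, p = X.shape
    G = Y.shape[1]
    nd = W.sum(axis=0)  # detected cells per gene
    H = np.einsum("np,ng,nq->gpq", X, W, X)  # G × p × p
    b = X.T @ (W * Y)  # p × G
    ok = nd > p
    beta = np.zeros((p, G))
    ll = np.zeros(G)
    rss = np.full(G, np.nan)
    if ok.any():
        Hok = H[ok] + 1e-12 * np.eye(p)[None, :, :]
        try:
            sol = np.linalg.solve(Hok, b.T[ok][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            sol = np.array([np.linalg.lstsq(h, bb, rcond=None)[0]
                            for h, bb in zip(Hok, b.T[ok])])
        beta[:, ok] = sol.T
        resid = W * (Y - X @ beta)
        rss = (resid ** 2).sum(axis=0)
        nd_ok = nd[ok]
        sigma2 = np.maximum(rss[ok] / nd_ok, 1e-12)
        ll[ok] = -0.5 * nd_ok * (np.log(2 * np.pi * sigma2) + 1.0)
    return beta, ll, ok, rss, nd


# ---------------------------------------------------------------------------
# single-gene interface
# ---------------------------------------------------------------------------

@dataclass
class HurdleFit:
    """A two-part hurdle model fit for one gene.

    ``logit_*`` describe the detection part (fit only when the detection
    indicator varies), ``lin_*`` the Gaussian level part on detected cells.
    The total log-likelihood is the sum of both parts.
    """

    logit_coef: np.ndarray | None
    logit_ll: float
    logit_df: int
    lin_coef: np.ndarray | None
    lin_ll: float
    lin_df: int
    sigma2: float
    n_cells: int
    n_detected: int
    columns: tuple[str, ...] | None = None
    flagged: bool = False

    @property
    def total_ll(self) -> float:
        return self.logit_ll + self.lin_ll


def fit_hurdle(y: np.ndarray, X: np.ndarray,
               columns: Sequence[str] | None = None) -> HurdleFit:
    """Fit the hurdle model for one gene: y are ln-normalized values, X the design."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y must be 1-D with one entry per design row")
    n, p = X.shape
    d = (y > 0).astype(float)
    n_det = int(d.sum())

    if 0 < n_det < n:
        lb, lll, lflag = _batch_logistic(X, d[:, None])
        logit_coef, logit_ll, logit_df = lb[:, 0], float(lll[0]), p
        flagged = bool(lflag[0])
    else:
        # detection constant: saturated probability 1, zero df
        logit_coef, logit_ll, logit_df, flagged = None, 0.0, 0, False

    gb, gll, gok, _grss, _gnd = _batch_gaussian(X, y[:, None], d[:, None])
    if bool(gok[0]):
        lin_coef, lin_ll, lin_df = gb[:, 0], float(gll[0]), p
        w = d
        resid = w * (y - X @ gb[:, 0])
        sigma2 = float(max((resid ** 2).sum() / max(n_det, 1), 1e-12))
    else:
        lin_coef, lin_ll, lin_df, sigma2 = None, 0.0, 0, float("nan")

    return HurdleFit(
        logit_coef=logit_coef, logit_ll=logit_ll, logit_df=logit_df,
        lin_coef=lin_coef, lin_ll=lin_ll, lin_df=lin_df, sigma2=sigma2,
        n_cells=n, n_detected=n_det,
        columns=tuple(columns) if columns is not None else None,
        flagged=flagged,
    )


def hurdle_lrt(full: HurdleFit, reduced: HurdleFit):
    """Likelihood-ratio test of nested hurdle fits: (chi2, df, p).

    The statistic sums both parts; df is the added parameter count across
    the parts that actually carry degrees of freedom.
    """
    if full.n_cells != reduced.n_cells or full.n_detected != reduced.n_detected:
        raise ValueError("fits are not on the same cells")
    if full.columns is not None and reduced.columns is not None:
        if not set(reduced.columns) <= set(full.columns):
            raise ValueError("reduced design is not nested in the full design")
    df = max(full.logit_df - reduced.logit_df, 0) + max(full.lin_df - reduced.lin_df, 0)
    chi2 = max(2.0 * (full.total_ll - reduced.total_ll), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def log2fc(nm: NormalizedMatrix, cells_a, cells_b) -> pd.Series:
    """Per-gene log2 fold change: difference of group means of ln values / ln 2.

    Group A is the numerator (tau, or the later timepoint).
    """
    ia = nm.cells.get_indexer(pd.Index(cells_a)) if not np.issubdtype(
        np.asarray(cells_a).dtype, np.integer) else np.asarray(cells_a)
    ib = nm.cells.get_indexer(pd.Index(cells_b)) if not np.issubdtype(
        np.asarray(cells_b).dtype, np.integer) else np.asarray(cells_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both groups must be non-empty")
    mean_a = nm.values[:, ia].mean(axis=1)
    mean_b = nm.values[:, ib].mean(axis=1)
    return pd.Series((mean_a - mean_b) / _LN2, index=nm.genes, name="avg_log2FC")


# ---------------------------------------------------------------------------
# contrast designs and the per-cluster test
# ---------------------------------------------------------------------------

@dataclass
class ContrastDesign:
    """A two-group contrast with covariates and a cell-scope restriction.

    ``levels`` orders the grouping variable as (numerator, denominator) —
    (tau, control) for the genotype contrast, (later age, earlier age) for
    an aging step within controls.  ``scope`` restricts cells by metadata
    column values before grouping.
    """

    grouping: str
    levels: tuple
    covariates: tuple[str, ...] = ("cdr",)
    scope: dict | None = None

    def __post_init__(self) -> None:
        if len(self.levels) != 2:
            raise ValueError("contrast grouping must have exactly 2 levels")


def tau_design(ages: Sequence[int] | None = None) -> ContrastDesign:
    """Age-adjusted tau-vs-control contrast (CDR + age covariates)."""
    scope = {"age": list(ages)} if ages is not None else None
    return ContrastDesign(grouping="genotype", levels=("tau", "control"),
                          covariates=("cdr", "age"), scope=scope)


def aging_design(age_pair: tuple[int, int]) -> ContrastDesign:
    """Consecutive-age contrast within control animals (CDR covariate).

    ``age_pair`` is (earlier, later); the later age is the numerator.
    """
    lo, hi = age_pair
    return ContrastDesign(grouping="age", levels=(hi, lo), covariates=("cdr",),
                          scope={"genotype": ["control"]})


def _scope_mask(meta: pd.DataFrame, scope: dict | None) -> np.ndarray:
    mask = np.ones(len(meta), dtype=bool)
    if scope:
        for col, allowed in scope.items():
            mask &= meta[col].isin(allowed).to_numpy()
    return mask


def de_test(
    nm: NormalizedMatrix,
    meta: pd.DataFrame,
    design: ContrastDesign,
    clusters: Sequence | None = None,
    min_cells: int = 10,
    padj_threshold: float = 0.05,
    lfc_threshold: float = 0.1,
    pct_threshold: float = 0.10,
) -> pd.DataFrame:
    """Hurdle-LRT differential expression per cluster for a two-group contrast.

    Genes are tested only when detected in at least ``pct_threshold`` of
    cells in one of the groups (this pre-filter coincides with the
    reporting filter).  BH correction is applied across genes within each
    cluster.  Returns one row per tested (gene, cluster) with the
    supplementary-table column vocabulary.
    """
    meta = meta.loc[nm.cells]
    if "cdr" in design.covariates and "cdr" not in meta.columns:
        meta = meta.copy()
        meta["cdr"] = (nm.values > 0).mean(axis=0)

    base_mask = _scope_mask(meta, design.scope)
    if clusters is None:
        clusters = sorted(pd.unique(meta.loc[base_mask, "cluster"]))

    frames = []
    for cl in clusters:
        mask = base_mask & (meta["cluster"] == cl).to_numpy()
        grp = meta.loc[mask, design.grouping]
        idx_all = np.flatnonzero(mask)
        a_lvl, b_lvl = design.levels
        ia = idx_all[(grp == a_lvl).to_numpy()]
        ib = idx_all[(grp == b_lvl).to_numpy()]
        if len(ia) < min_cells or len(ib) < min_cells:
            log.info("cluster %s skipped: groups of size %d/%d below %d",
                     cl, len(ia), len(ib), min_cells)
            continue
        idx = np.concatenate([ia, ib])
        Y = nm.values[:, idx].T  # cells × genes
        D = (Y > 0).astype(float)

        pct1 = D[: len(ia)].mean(axis=0)
        pct2 = D[len(ia):].mean(axis=0)
        tested = np.maximum(pct1, pct2) >= pct_threshold
        if not tested.any():
            continue
        Yt, Dt = Y[:, tested], D[:, tested]

        group = np.r_[np.ones(len(ia)), np.zeros(len(ib))]
        cols = [np.ones(len(idx)), group]
        for cov in design.covariates:
            v = meta.iloc[idx][cov].to_numpy(dtype=float)
            if cov == "cdr":
                # centre CDR within each group: strong expression changes
                # leak into the global detection rate, and a genotype-
                # contaminated covariate makes unchanged genes load on the
                # group coefficient; centring keeps CDR purely technical
                v = v.copy()
                v[: len(ia)] -= v[: len(ia)].mean()
                v[len(ia):] -= v[len(ia):].mean()
            # standardize covariates for Newton conditioning (LL-invariant)
            sd = v.std()
            cols.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
        X_full = np.column_stack(cols)
        X_red = np.delete(X_full, 1, axis=1)

        chi2, df, flagged = _lrt_batch(X_full, X_red, Yt, Dt)
        with np.errstate(invalid="ignore"):
            p = np.where(df > 0, stats.chi2.sf(chi2, np.maximum(df, 1)), 1.0)
        padj = multipletests(p, method="fdr_bh")[1]
        lfc = (Yt[: len(ia)].mean(axis=0) - Yt[len(ia):].mean(axis=0)) / _LN2

        genes = nm.genes[tested]
        sig = (padj < padj_threshold) & (np.abs(lfc) > lfc_threshold) & \
              (np.maximum(pct1[tested], pct2[tested]) >= pct_threshold)
        frames.append(pd.DataFrame({
            "gene": genes,
            "cluster": cl,
            "avg_log2FC": lfc,
            "pct.1": pct1[tested],
            "pct.2": pct2[tested],
            "p_val": p,
            "padj": padj,
            "direction": np.where(lfc >= 0, "up", "down"),
            "significant": sig,
            "flagged": flagged,
        }))
    if not frames:
        return pd.DataFrame(columns=["gene", "cluster", "avg_log2FC", "pct.1",
                                     "pct.2", "p_val", "padj", "direction",
                                     "significant", "flagged"])
    return pd.concat(frames, ignore_index=True)


def _lrt_batch(X_full, X_red, Y, D):
    """Vectorized hurdle LRT of full vs reduced for many genes on fixed designs."""
    n, pf = X_full.shape
    pr = X_red.shape[1]
    G = Y.shape[1]
    det_var = (D.sum(axis=0) > 0) & (D.sum(axis=0) < n)

    llf_logit = np.zeros(G)
    llr_logit = np.zeros(G)
    flagged = np.zeros(G, dtype=bool)
    if det_var.any():
        Dv = D[:, det_var]
        _, llf, fl1 = _batch_logistic(X_full, Dv)
        _, llr, fl2 = _batch_logistic(X_red, Dv)
        llf_logit[det_var] = llf
        llr_logit[det_var] = llr
        flagged[det_var] = fl1 | fl2

    _, _llf_lin, okf, rss_f, nd = _batch_gaussian(X_full, Y, D)
    _, _llr_lin, okr, rss_r, _ = _batch_gaussian(X_red, Y, D)
    ok = okf & okr & (rss_f > 0)

    # level part calibrated through the exact F distribution on the
    # detected subset (finite-sample correction of the Gaussian LRT),
    # converted back to a chi-square-equivalent so the two parts sum
    q = pf - pr
    chi2_lin = np.zeros(G)
    if ok.any():
        df2 = nd[ok] - pf
        F = ((rss_r[ok] - rss_f[ok]) / q) / (rss_f[ok] / df2)
        pF = np.clip(stats.f.sf(np.maximum(F, 0.0), q, df2), 1e-300, 1.0)
        chi2_lin[ok] = stats.chi2.isf(pF, q)

    chi2 = np.zeros(G)
    df = np.zeros(G, dtype=int)
    chi2 += np.where(det_var, 2.0 * (llf_logit - llr_logit), 0.0)
    df += np.where(det_var, pf - pr, 0)
    chi2 += np.where(ok, chi2_lin, 0.0)
    df += np.where(ok, q, 0)
    return np.maximum(chi2, 0.0), df, flagged


# ---------------------------------------------------------------------------
# tau / aging overlap
# ---------------------------------------------------------------------------

def significant_gene_sets(de_table: pd.DataFrame) -> dict:
    """Per-cluster sets of significant genes from a de_test result table."""
    sig = de_table[de_table["significant"]]
    return {cl: set(sub["gene"]) for cl, sub in sig.groupby("cluster")}


def overlap_statistic(tau_de: Mapping, aging_de: Mapping):
    """Fraction of tau-responsive genes that are also aging-responsive.

    Returns (global fraction, per-cluster fractions).  The global fraction
    pools unique genes over clusters; a cluster's fraction is computed only
    where both maps name the cluster.  An empty tau union yields None.
    """
    tau_union = set().union(*tau_de.values()) if tau_de else set()
    aging_union = set().union(*aging_de.values()) if aging_de else set()
    global_frac = (
        len(tau_union & aging_union) / len(tau_union) if tau_union else None
    )
    per_cluster = {}
    for cl in set(tau_de) & set(aging_de):
        t = set(tau_de[cl])
        per_cluster[cl] = len(t & set(aging_de[cl])) / len(t) if t else None
    return global_frac, per_cluster
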