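"""Differential cell-type abundance with reference-class anchoring.

Per-library cell counts per cluster are treated as count data: library size
factors come from the median-of-ratios against row geometric means, each
cluster's counts are fit with a negative-binomial GLM
(count ~ age + genotype, log link, size factors as offsets) and the
genotype coefficient is Wald-tested with BH correction across clusters.
Because single-cell composition is closed (proportions sum to one), an
anchored analysis subtracts each reference-class (glial) cluster's log2FC
from every cluster, yielding a [min, max] range that brackets the true
change under the assumption that the anchors are unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "ClusterCountTable",
    "AbundanceRecord",
    "AnchoredRange",
    "count_cells",
    "size_factors",
    "fit_abundance",
    "shrink_lfc",
    "anchor_adjust",
]

_LN2 = np.log(2.0)


@dataclass
class ClusterCountTable:
    """Clusters × libraries cell counts with per-library annotations."""

    counts: pd.DataFrame  # clusters × libraries, non-negative integers
    library_meta: pd.DataFrame  # one row per library: genotype, age, replicate

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.library_meta.index):
            self.library_meta = self.library_meta.loc[self.counts.columns]


def count_cells(meta: pd.DataFrame) -> ClusterCountTable:
    """Cross-tabulate cells into a clusters × libraries count table."""
    for col in ("library", "cluster"):
        if col not in meta.columns or meta[col].isna().any():
            raise ValueError(f"every cell needs a '{col}' label")
    tab = pd.crosstab(meta["cluster"], meta["library"])
    lib_meta = (
        meta.groupby("library")[
            [c for c in ("genotype", "age", "replicate") if c in meta.columns]
        ]
        .first()
        .loc[tab.columns]
    )
    return ClusterCountTable(counts=tab, library_meta=lib_meta)


def size_factors(tbl: ClusterCountTable | pd.DataFrame,
                 pseudocount: float | None = None) -> pd.Series:
    """Median-of-ratios library size factors.

    Rows (clusters) containing any zero are excluded from the
    geometric-mean reference; ``pseudocount`` (e.g. 0.5) can be added to
    every entry instead when too few rows are all-positive.
    """
    counts = tbl.counts if isinstance(tbl, ClusterCountTable) else tbl
    mat = counts.to_numpy(dtype=float)
    if pseudocount:
        mat = mat + pseudocount
    eligible = (mat > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no all-positive clusters for the geometric-mean reference; "
            "consider pseudocount=0.5"
        )
    sub = mat[eligible]
    geomean = np.exp(np.log(sub).mean(axis=1))
    ratios = sub / geomean[:, None]
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


@dataclass
class AbundanceRecord:
    cluster: str
    baseMean: float
    log2FC: float
    lfcSE: float
    p: float
    padj: float = np.nan
    shrunk_log2FC: float | None = None


def _nb_loglik(y, X, offset, alpha):
    """Profile NB log-likelihood at dispersion alpha (Cox-Reid adjusted)."""
    fam = sm.families.NegativeBinomial(alpha=alpha)
    try:
        res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
    except Exception:
        return -np.inf, None
    mu = res.fittedvalues
    size = 1.0 / alpha
    ll = stats.nbinom.logpmf(y, size, size / (size + mu)).sum()
    # Cox-Reid adjustment guards the n-of-libraries-scale downward bias
    W = mu / (1.0 + alpha * mu)
    XtWX = X.T @ (W[:, None] * X)
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, None
    return ll - 0.5 * logdet, res


def _estimate_dispersion(y, X, offset):
    """Per-cluster dispersion: adjusted-profile ML with a moments fallback."""
    # method-of-moments start: var = mu + alpha * mu^2 around the design means
    pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    mu = pois.fittedvalues
    resid2 = (y - mu) ** 2
    mom = max((resid2 - mu).sum() / max((mu ** 2).sum(), 1e-12), 1e-8)

    def neg_apl(log_alpha):
        ll, _ = _nb_loglik(y, X, offset, np.exp(log_alpha))
        return -ll

    try:
        res = optimize.minimize_scalar(
            neg_apl, bounds=(np.log(1e-8), np.log(50.0)), method="bounded",
            options={"xatol": 1e-3},
        )
        alpha = float(np.exp(res.x)) if np.isfinite(res.fun) else mom
    except Exception:
        alpha = mom
    return max(alpha, 1e-8)


def fit_abundance(tbl: ClusterCountTable, design: str = "age+genotype",
                  size_factor_pseudocount: float | None = None) -> pd.DataFrame:
    """NB-GLM differential abundance, one record per cluster.

    ``design`` is "age+genotype" (discovery: ages pooled as replicates) or
    "genotype" (replication design).  The Wald test is on the genotype
    coefficient; log2FC is that coefficient divided by ln 2; BH across
    clusters.  All-zero clusters yield records with missing statistics.
    """
    counts = tbl.counts
    lib = tbl.library_meta
    if design not in ("age+genotype", "genotype"):
        raise ValueError(f"unknown design {design!r}")
    genos = lib["genotype"].unique()
    for g in ("control", "tau"):
        if (lib["genotype"] == g).sum() < 2:
            raise ValueError(f"need >=2 libraries of genotype {g!r}")

    s = size_factors(tbl, pseudocount=size_factor_pseudocount)
    offset = np.log(s.to_numpy())
    geno = (lib["genotype"] == "tau").to_numpy(dtype=float)
    cols = [np.ones(len(lib))]
    names = ["intercept"]
    if design == "age+genotype":
        cols.append(lib["age"].to_numpy(dtype=float))
        names.append("age")
    cols.append(geno)
    names.append("genotype")
    X = np.column_stack(cols)
    gi = names.index("genotype")

    norm = counts.to_numpy(dtype=float) / s.to_numpy()[None, :]
    records = []
    for r, cl in enumerate(counts.index):
        y = counts.iloc[r].to_numpy(dtype=float)
        base_mean = float(norm[r].mean())
        if y.sum() == 0:
            records.append(AbundanceRecord(cl, 0.0, np.nan, np.nan, np.nan))
            continue
        alpha = _estimate_dispersion(y, X, offset)
        ll, res = _nb_loglik(y, X, offset, alpha)
        if res is None:
            records.append(AbundanceRecord(cl, base_mean, np.nan, np.nan, np.nan))
            continue
        coef = res.params[gi]
        se = np.sqrt(res.cov_params()[gi, gi])
        z = coef / se if se > 0 else np.nan
        p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        records.append(AbundanceRecord(
            cluster=cl, baseMean=base_mean,
            log2FC=float(coef / _LN2), lfcSE=float(se / _LN2), p=p,
        ))

    out = pd.DataFrame([vars(rec) for rec in records]).set_index("cluster")
    tested = out["p"].notna()
    out.loc[tested, "padj"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out.attrs["size_factors"] = s
    out.attrs["design"] = design
    return out


def shrink_lfc(records: pd.DataFrame) -> pd.DataFrame:
    """Single-normal empirical-Bayes shrinkage of log2FC toward zero.

    Prior variance = max(0, var(log2FC) - mean(lfcSE^2)); each estimate is
    scaled by priorVar / (priorVar + lfcSE^2).  With fewer than three
    usable clusters the raw values pass through with a warning.
    """
    out = records.copy()
    usable = out["log2FC"].notna() & out["lfcSE"].notna()
    if usable.sum() < 3:
        warnings.warn("fewer than 3 clusters: shrinkage skipped, raw values kept")
        out["shrunk_log2FC"] = out["log2FC"]
        return out
    lfc = out.loc[usable, "log2FC"].to_numpy()
    se2 = out.loc[usable, "lfcSE"].to_numpy() ** 2
    prior_var = max(0.0, float(np.var(lfc)) - float(np.mean(se2)))
    out.loc[usable, "shrunk_log2FC"] = lfc * prior_var / (prior_var + se2)
    return out


@dataclass
class AnchoredRange:
    cluster: str
    min_log2FC: float
    max_log2FC: float
    excludes_zero: bool


def anchor_adjust(records: pd.DataFrame, anchor_clusters) -> pd.DataFrame:
    """Anchor-adjusted log2FC ranges.

    Each anchor cluster's log2FC is subtracted from every cluster's value;
    the min and max of those differences bound the true change under the
    assumption the anchors are unchanged.  Anchors themselves include 0 via
    self-subtraction.
    """
    anchors = [a for a in anchor_clusters]
    if not anchors:
        raise ValueError("anchor set must be non-empty")
    missing = set(anchors) - set(records.index)
    if missing:
        raise ValueError(f"anchors not in records: {sorted(missing)}")
    anchor_vals = records.loc[anchors, "log2FC"].to_numpy()
    rows = []
    for cl in records.index:
        v = records.loc[cl, "log2FC"]
        cand = v - anchor_vals
        lo, hi = float(np.min(cand)), float(np.max(cand))
        rows.append(AnchoredRange(cl, lo, hi, excludes_zero=(lo > 0 or hi < 0)))
    out = pd.DataFrame([vars(r) for r in rows]).set_index("cluster")
    return out
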