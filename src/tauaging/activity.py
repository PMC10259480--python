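"""Gene-set activity scoring and differential activity.

Two per-cell scores: the mean of member-gene ln-normalized expression, and
an AUCell-style ranking-recovery AUC — genes ranked by expression within
each cell (descending, ties broken by ascending gene index), the
cumulative recovery of set members tallied over the top 5% of ranks, and
the area under that curve normalized to [0, 1].  Cluster-level genotype
contrasts use log2 ratio-of-means, and a Gaussian likelihood-ratio test of
Activity ~ genotype + age against Activity ~ age scores differential
activity per (cluster, set) with BH correction across sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet
from .qc import NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ActivityMatrix",
    "mean_activity",
    "auc_activity",
    "auc_recovery_curve",
    "cluster_activity_lfc",
    "differential_activity",
]

_LN2 = np.log(2.0)


@dataclass
class ActivityMatrix:
    """Cells × gene-sets activity values with a method tag."""

    values: pd.DataFrame  # cells × sets
    method: str  # "mean" | "auc"
    sets: list = field(default_factory=list)
    frac_present: dict = field(default_factory=dict)

    @property
    def cells(self) -> pd.Index:
        return self.values.index


def _present_members(nm: NormalizedMatrix, s: GeneSet):
    idx = nm.genes.get_indexer(pd.Index(s.genes))
    present = idx[idx >= 0]
    return present, len(present) / max(len(s.genes), 1)


def mean_activity(nm: NormalizedMatrix, sets: list[GeneSet]) -> ActivityMatrix:
    """Per-cell mean expression of each set's present members."""
    cols = {}
    frac = {}
    for s in sets:
        present, f = _present_members(nm, s)
        frac[s.name] = f
        if len(present) == 0:
            warnings.warn(f"gene set '{s.name}' has no members in the gene universe")
            cols[s.name] = np.full(nm.n_cells, np.nan)
            continue
        cols[s.name] = nm.values[present].mean(axis=0)
    values = pd.DataFrame(cols, index=nm.cells)
    return ActivityMatrix(values=values, method="mean", sets=list(sets),
                          frac_present=frac)


def auc_recovery_curve(expr: np.ndarray, member_idx: np.ndarray,
                       k_max: int) -> np.ndarray:
    """Brute-force cumulative recovery curve of one cell (oracle-style).

    Returns recovery(i) for i = 1..k_max, where recovery(i) counts set
    members among the top-i ranked genes.  Ties are broken by ascending
    gene index.
    """
    order = np.lexsort((np.arange(expr.size), -expr))
    members = np.zeros(expr.size, dtype=bool)
    members[member_idx] = True
    hits = members[order[:k_max]]
    return np.cumsum(hits)


def _auc_denominator(n_members: int, k_max: int, normalization: str) -> float:
    if normalization == "A":
        return float(k_max * min(n_members, k_max))
    if normalization == "B":
        # area of the best possible curve: all members ranked on top
        m = min(n_members, k_max)
        return float(m * k_max - m * (m - 1) / 2.0)
    raise ValueError(f"unknown normalization mode {normalization!r}")


def auc_activity(nm: NormalizedMatrix, sets: list[GeneSet],
                 top_fraction: float = 0.05,
                 normalization: str = "B") -> ActivityMatrix:
    """AUCell-style ranking-recovery activity in [0, 1] per cell and set.

    ``normalization`` "A" divides the curve area by k_max * min(|S|, k_max);
    "B" (default) divides by the area of the best achievable curve.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    G = nm.n_genes
    k_max = int(np.floor(top_fraction * G))
    if k_max == 0:
        raise ValueError("top_fraction * n_genes < 1: no ranks to recover over")

    # rank of each gene in each cell (0 = highest expression; ties by index)
    gene_idx = np.arange(G)
    ranks = np.empty((G, nm.n_cells), dtype=np.int32)
    for c in range(nm.n_cells):
        order = np.lexsort((gene_idx, -nm.values[:, c]))
        ranks[order, c] = gene_idx
    cols = {}
    frac = {}
    for s in sets:
        present, f = _present_members(nm, s)
        frac[s.name] = f
        if len(present) == 0:
            warnings.warn(f"gene set '{s.name}' has no members in the gene universe")
            cols[s.name] = np.full(nm.n_cells, np.nan)
            continue
        r = ranks[present]  # members × cells
        # member at rank r (0-based, r < k_max) contributes (k_max - r) to the
        # summed recovery curve sum_{i=1..k_max} recovery(i)
        contrib = np.where(r < k_max, k_max - r, 0).sum(axis=0)
        denom = _auc_denominator(len(present), k_max, normalization)
        cols[s.name] = contrib / denom
    values = pd.DataFrame(cols, index=nm.cells)
    return ActivityMatrix(values=values, method="auc", sets=list(sets),
                          frac_present=frac)


def cluster_activity_lfc(act: ActivityMatrix, meta: pd.DataFrame,
                         grouping: str = "genotype",
                         levels: tuple = ("tau", "control")) -> pd.DataFrame:
    """Per (cluster, set) log2 ratio of mean activity, numerator first.

    Requires non-negative activities (lognorm means or AUC); a non-positive
    group mean yields a missing value.
    """
    if act.method not in ("mean", "auc"):
        raise ValueError("cluster_activity_lfc needs mean or auc activities")
    meta = meta.loc[act.cells]
    a_lvl, b_lvl = levels
    rows = {}
    for cl, sub in meta.groupby("cluster"):
        in_a = sub.index[sub[grouping] == a_lvl]
        in_b = sub.index[sub[grouping] == b_lvl]
        if len(in_a) == 0 or len(in_b) == 0:
            continue
        ma = act.values.loc[in_a].mean(axis=0)
        mb = act.values.loc[in_b].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.where((ma > 0) & (mb > 0), np.log2(ma / mb), np.nan)
        rows[cl] = pd.Series(lfc, index=act.values.columns)
    return pd.DataFrame(rows).T  # clusters × sets


def differential_activity(act: ActivityMatrix, meta: pd.DataFrame,
                          min_cells: int = 10) -> pd.DataFrame:
    """Genotype LRT on activity per (cluster, set): full ~ genotype + age
    versus reduced ~ age, 1 df, BH across sets within each cluster."""
    meta = meta.loc[act.cells]
    records = []
    for cl, sub in meta.groupby("cluster"):
        if len(sub) < min_cells:
            continue
        geno = (sub["genotype"] == "tau").to_numpy(dtype=float)
        if geno.min() == geno.max():
            continue
        age = sub["age"].to_numpy(dtype=float)
        n = len(sub)
        X_full = np.column_stack([np.ones(n), age, geno])
        X_red = X_full[:, :2]
        A = act.values.loc[sub.index].to_numpy()  # n × sets
        for j, set_name in enumerate(act.values.columns):
            y = A[:, j]
            if np.isnan(y).any():
                records.append((cl, set_name, np.nan, np.nan))
                continue
            rss_f = _rss(X_full, y)
            rss_r = _rss(X_red, y)
            if rss_f <= 0 or rss_r <= 0:
                records.append((cl, set_name, np.nan, np.nan))
                continue
            chi2 = n * np.log(rss_r / rss_f)
            p = float(stats.chi2.sf(max(chi2, 0.0), 1))
            records.append((cl, set_name, max(chi2, 0.0), p))
    out = pd.DataFrame(records, columns=["cluster", "set", "chi2", "p"])
    out["padj"] = np.nan
    for cl, sub in out.groupby("cluster"):
        tested = sub["p"].notna()
        if tested.any():
            out.loc[sub.index[tested], "padj"] = multipletests(
                sub.loc[tested, "p"], method="fdr_bh")[1]
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)
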