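"""Cross-species cluster correspondence and gene-set overlap.

Orthologs are resolved one candidate per source gene by a priority cascade
(minimum score 5, then highest score, highest weighted score,
best-bidirectional flag, lexicographic target).  Cluster-level mean
z-scored profiles from two datasets are correlated (Pearson) over the
resolved ortholog features for every cluster pair, with average-linkage
seriation on 1 - r for display order.  Differential gene-set overlap is
tested with the upper-tail hypergeometric distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .qc import NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "select_orthologs",
    "cluster_mean_profiles",
    "correspondence",
    "overlap_test",
]


def select_orthologs(table: pd.DataFrame, min_score: int = 5,
                     strict_injection: bool = False) -> pd.DataFrame:
    """Resolve each source gene to at most one target by the priority cascade.

    Candidates below ``min_score`` are dropped; the survivor with the
    highest score wins, ties broken by highest weighted score, then the
    best-forward-and-reverse flag, then lexicographically smallest target
    (flagged as an arbitrary tie-break).  With ``strict_injection`` a
    target claimed by several sources keeps only the best-scoring source.
    Row order of the input is irrelevant.
    """
    required = {"human_gene", "fly_gene", "score", "weighted_score",
                "best_forward", "best_reverse"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ortholog table lacks columns: {sorted(missing)}")
    t = table[table["score"] >= min_score].copy()
    t["best_both"] = t["best_forward"].astype(bool) & t["best_reverse"].astype(bool)
    t = t.sort_values(
        by=["human_gene", "score", "weighted_score", "best_both", "fly_gene"],
        ascending=[True, False, False, False, True],
        kind="mergesort",
    )
    picked = t.groupby("human_gene", sort=True).head(1).copy()
    runner = t.groupby("human_gene", sort=True).nth(1)
    tie_sources = set()
    if runner is not None and len(runner):
        merged = picked.merge(
            runner, on="human_gene", suffixes=("", "_r"), how="inner")
        tie = (
            (merged["score"] == merged["score_r"])
            & (merged["weighted_score"] == merged["weighted_score_r"])
            & (merged["best_both"] == merged["best_both_r"])
        )
        tie_sources = set(merged.loc[tie, "human_gene"])
    picked["tie_broken_lexicographic"] = picked["human_gene"].isin(tie_sources)
    if strict_injection:
        picked = picked.sort_values(
            by=["fly_gene", "score", "weighted_score", "best_both", "human_gene"],
            ascending=[True, False, False, False, True], kind="mergesort",
        ).groupby("fly_gene", sort=True).head(1)
    cols = ["human_gene", "fly_gene", "score", "weighted_score",
            "best_both", "tie_broken_lexicographic"]
    return picked[cols].sort_values("human_gene").reset_index(drop=True)


def cluster_mean_profiles(nm: NormalizedMatrix, clusters: pd.Series
                          ) -> pd.DataFrame:
    """Cluster × gene matrix of mean z-scored expression."""
    if nm.transform != "zscore":
        raise ValueError("cluster_mean_profiles expects a z-scored matrix")
    clusters = clusters.loc[nm.cells]
    rows = {}
    for cl, cells in clusters.groupby(clusters):
        idx = nm.cells.get_indexer(cells.index)
        rows[cl] = nm.values[:, idx].mean(axis=1)
    return pd.DataFrame(rows, index=nm.genes).T


def correspondence(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame,
                   mapping: pd.DataFrame | None = None,
                   source_col: str = "human_gene", target_col: str = "fly_gene"):
    """Pearson correlation of every (A-cluster, B-cluster) profile pair.

    ``mapping`` pairs A-dataset genes (``source_col``) to B-dataset genes
    (``target_col``); None means shared gene names.  Returns
    (CorrespondenceMatrix DataFrame, row order, column order) where the
    orders come from average-linkage seriation on 1 - r.
    """
    if mapping is None:
        shared = profiles_a.columns.intersection(profiles_b.columns)
        src = tgt = list(shared)
    else:
        pairs = [(s, t) for s, t in zip(mapping[source_col], mapping[target_col])
                 if s in profiles_a.columns and t in profiles_b.columns]
        src = [s for s, _ in pairs]
        tgt = [t for _, t in pairs]
    if len(src) < 3:
        raise ValueError("need at least 3 shared mapped features")
    A = profiles_a.loc[:, src].to_numpy()
    B = profiles_b.loc[:, tgt].to_numpy()
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1, keepdims=True)
    nb = np.linalg.norm(Bc, axis=1, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    R = (Ac / na) @ (Bc / nb).T
    mat = pd.DataFrame(R, index=profiles_a.index, columns=profiles_b.index)
    row_order = _seriate(mat.to_numpy())
    col_order = _seriate(mat.to_numpy().T)
    return mat, list(mat.index[row_order]), list(mat.columns[col_order])


def _seriate(R: np.ndarray) -> np.ndarray:
    """Average-linkage leaf order on distance 1 - r between rows of R."""
    if R.shape[0] < 3:
        return np.arange(R.shape[0])
    # distance between rows: 1 - correlation of their correlation profiles
    C = np.corrcoef(R)
    D = np.clip(1.0 - C, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return np.asarray(hierarchy.leaves_list(Z))


def overlap_test(set_a, set_b, universe):
    """Upper-tail hypergeometric test of the overlap of two gene sets.

    Population = |universe|, successes = |A|, draws = |B|;
    p = P(X >= |A ∩ B|).  Both sets must lie within the universe.
    """
    A, B, U = set(set_a), set(set_b), set(universe)
    if not A <= U or not B <= U:
        raise ValueError("sets must be subsets of the universe")
    k = len(A & B)
    p = float(stats.hypergeom.sf(k - 1, len(U), len(A), len(B)))
    return k, p
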