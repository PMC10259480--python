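"""Consensus cell-type annotation against reference atlases.

Four evidence channels are consolidated per query cluster: (1) cell-level
centroid-similarity mapping (cosine, Spearman and Pearson over ~500
high-dropout features; a cell maps to a reference cluster when two of the
three measures agree on it and at least one voting score exceeds 0.7),
lifted to cluster level by the majority mapped reference covering more than
half of mapped cells; (2) intersection of the top-20 positive markers with
each reference cluster's top-20 (mapped at >= 13/20 shared for a
whole-brain reference, >= 7/20 for an optic-lobe reference); (3) an
optional external classifier label table; (4) an optional literature-marker
checklist.  A label supported by two or more channels is a consensus call;
one channel gives a single-source call; none leaves the cluster
unannotated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset
from .qc import NormalizedMatrix
from . import de as _de

log = logging.getLogger(__name__)

__all__ = [
    "ReferenceAtlas",
    "AnnotationEvidence",
    "cluster_markers",
    "select_dropout_features",
    "compute_similarities",
    "map_cell",
    "map_cells",
    "marker_overlap_map",
    "consolidate_annotations",
    "build_reference_atlas",
    "annotate_clusters",
]


@dataclass
class ReferenceAtlas:
    """Cluster centroids, top markers and similarity features of a reference."""

    centroids: pd.DataFrame  # clusters × genes mean lognorm expression
    top_markers: dict  # cluster -> ranked marker list (top k)
    features: list  # gene ids used for similarity scoring
    full_markers: dict = field(default_factory=dict)  # cluster -> full ranked list
    source: str = "reference"

    def __post_init__(self) -> None:
        if self.centroids.loc[:, self.features].isna().any().any():
            raise ValueError("centroids contain missing values over the feature list")


def cluster_markers(nm: NormalizedMatrix, clusters: pd.Series, top_k: int = 20,
                    min_cells: int = 10, lfc_threshold: float = 0.1,
                    padj_threshold: float = 0.05,
                    max_rest_cells: int = 2000) -> dict:
    """One-vs-rest positive markers per cluster, ranked by descending log2FC.

    Returns {cluster: (top_k list, full ranked list)}.  Only genes with
    positive log2FC above the threshold and BH-adjusted p below threshold
    qualify.  Clusters smaller than ``min_cells`` get empty lists with a
    warning in the log.  The "rest" group is capped at ``max_rest_cells``
    by a deterministic evenly-spaced subsample to keep large datasets
    tractable.
    """
    clusters = clusters.loc[nm.cells]
    labels = pd.unique(clusters)
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters for one-vs-rest markers")
    meta = pd.DataFrame({"cluster": clusters})
    meta["cdr"] = (nm.values > 0).mean(axis=0)
    out = {}
    for cl in labels:
        in_cl = (clusters == cl).to_numpy()
        if in_cl.sum() < min_cells:
            log.warning("cluster %s below %d cells: empty marker list", cl, min_cells)
            out[cl] = ([], [])
            continue
        rest_idx = np.flatnonzero(~in_cl)
        if len(rest_idx) > max_rest_cells:
            keep_rest = rest_idx[np.linspace(0, len(rest_idx) - 1,
                                             max_rest_cells).round().astype(int)]
        else:
            keep_rest = rest_idx
        use = np.sort(np.r_[np.flatnonzero(in_cl), keep_rest])
        ovr = meta.iloc[use].copy()
        ovr["ovr"] = np.where(in_cl[use], "this", "rest")
        design = _de.ContrastDesign(grouping="ovr", levels=("this", "rest"),
                                    covariates=("cdr",))
        ovr["cluster"] = "all"
        sub_nm = NormalizedMatrix(values=nm.values[:, use], genes=nm.genes,
                                  cells=nm.cells[use], transform=nm.transform,
                                  scale_constant=nm.scale_constant)
        table = _de.de_test(sub_nm, ovr, design, clusters=["all"],
                            min_cells=min_cells,
                            padj_threshold=padj_threshold,
                            lfc_threshold=lfc_threshold)
        pos = table[(table["padj"] < padj_threshold)
                    & (table["avg_log2FC"] > lfc_threshold)]
        ranked = pos.sort_values("avg_log2FC", ascending=False)["gene"].tolist()
        out[cl] = (ranked[:top_k], ranked)
    return out


def select_dropout_features(ds: Dataset, n_features: int = 500) -> list:
    """Genes with higher-than-expected dropout given their mean expression.

    Fits logit(dropout rate) linearly on log mean expression and returns
    the ``n_features`` genes with the largest positive residuals.  Genes
    with no dropouts are never selected before genes with positive
    residuals.
    """
    import warnings as _w

    counts = ds.counts
    n_cells = ds.n_cells
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    mean_expr = np.asarray(counts.sum(axis=1)).ravel() / n_cells
    eligible = mean_expr > 0
    n_eligible = int(eligible.sum())
    if n_features > n_eligible:
        _w.warn(f"only {n_eligible} expressed genes for {n_features} requested")
        n_features = n_eligible
    dropout = 1.0 - detected / n_cells
    eps = 1.0 / (2.0 * n_cells)
    d = np.clip(dropout, eps, 1.0 - eps)
    x = np.log(np.maximum(mean_expr, 1e-12))
    ylogit = np.log(d / (1.0 - d))
    A = np.column_stack([np.ones(x.size), x])
    beta, *_ = np.linalg.lstsq(A[eligible], ylogit[eligible], rcond=None)
    resid = ylogit - A @ beta
    resid[~eligible] = -np.inf
    resid[dropout == 0] = -np.inf  # nothing unexpected about zero dropout
    order = np.argsort(-resid, kind="stable")
    return [ds.genes[i] for i in order[:n_features]]


def compute_similarities(profiles: np.ndarray, centroids: np.ndarray):
    """Cosine, Pearson and Spearman similarity of each profile to each centroid.

    ``profiles`` is cells × features, ``centroids`` is clusters × features.
    Returns a dict of cells × clusters arrays.
    """
    def _cosine(A, B):
        na = np.linalg.norm(A, axis=1, keepdims=True)
        nb = np.linalg.norm(B, axis=1, keepdims=True)
        na[na == 0] = 1.0
        nb[nb == 0] = 1.0
        return (A / na) @ (B / nb).T

    def _pearson(A, B):
        A = A - A.mean(axis=1, keepdims=True)
        B = B - B.mean(axis=1, keepdims=True)
        return _cosine(A, B)

    ranks_p = np.apply_along_axis(stats.rankdata, 1, profiles)
    ranks_c = np.apply_along_axis(stats.rankdata, 1, centroids)
    return {
        "cosine": _cosine(profiles, centroids),
        "pearson": _pearson(profiles, centroids),
        "spearman": _pearson(ranks_p, ranks_c),
    }


def map_cell(scores: dict, threshold: float = 0.7):
    """Vote-based mapping of one cell from its per-measure similarity vectors.

    Each measure votes for its argmax reference (abstaining on exact ties);
    the cell maps to R when at least two measures vote R and the highest
    score among the voting measures exceeds ``threshold``.  Returns the
    reference column index or None.
    """
    votes = {}
    for measure, vec in scores.items():
        vec = np.asarray(vec, dtype=float)
        top = vec.max()
        winners = np.flatnonzero(vec == top)
        if len(winners) != 1:
            continue  # tie -> abstain
        votes.setdefault(int(winners[0]), []).append(top)
    for ref, tops in votes.items():
        if len(tops) >= 2 and max(tops) > threshold:
            return ref
    return None


def map_cells(nm: NormalizedMatrix, atlas: ReferenceAtlas,
              threshold: float = 0.7) -> pd.Series:
    """Vectorized map_cell over all cells; values are reference labels or None."""
    feats = [f for f in atlas.features if f in nm.genes]
    gi = nm.genes.get_indexer(pd.Index(feats))
    profiles = nm.values[gi].T  # cells × features
    centroids = atlas.centroids.loc[:, feats].to_numpy()
    sims = compute_similarities(profiles, centroids)
    ref_labels = atlas.centroids.index
    out = []
    for c in range(profiles.shape[0]):
        ref = map_cell({m: sims[m][c] for m in sims}, threshold=threshold)
        out.append(ref_labels[ref] if ref is not None else None)
    return pd.Series(out, index=nm.cells, name="scmap")


def marker_overlap_map(query_top: list, ref_tops: dict, min_shared: int = 13,
                       ref_full: dict | None = None):
    """Best reference by shared top markers; mapped only at >= min_shared.

    Ties on shared count break by Jaccard over the full marker lists, then
    lexicographically (tie flag set).  Returns (reference or None, shared
    count, tied flag).
    """
    if not query_top:
        return None, 0, False
    qset = set(query_top)
    best = []
    for ref, top in ref_tops.items():
        shared = len(qset & set(top))
        full = set((ref_full or {}).get(ref, top))
        qfull = qset
        union = len(qfull | full)
        jac = len(qfull & full) / union if union else 0.0
        best.append((shared, jac, ref))
    best.sort(key=lambda t: (-t[0], -t[1], t[2]))
    shared, jac, ref = best[0]
    tied = len(best) > 1 and best[1][0] == shared and best[1][1] == jac
    if shared >= min_shared:
        return ref, shared, tied
    return None, shared, False


@dataclass
class AnnotationEvidence:
    """Per-query-cluster channel results feeding consolidation."""

    cluster: str
    scmap_label: str | None = None  # majority mapped reference (>50% coverage)
    scmap_coverage: float = 0.0
    marker_label: str | None = None
    marker_shared: int = 0
    classifier_label: str | None = None
    checklist_label: str | None = None
    optic_lobe: bool = False  # channel family eligible for optic-lobe priority


def consolidate_annotations(evidence: list[AnnotationEvidence],
                            prioritize_optic_lobe: bool = False) -> pd.DataFrame:
    """Combine evidence channels into final labels with confidence tiers.

    Two or more channels agreeing give (label, 'consensus'); exactly one
    populated channel gives 'single-source'; conflicting pairs or nothing
    give 'unannotated'.  With ``prioritize_optic_lobe``, conflicts for
    flagged cluster families resolve toward the optic-lobe-derived
    (classifier) label.
    """
    rows = []
    for ev in evidence:
        labels = [lab for lab in (ev.scmap_label, ev.marker_label,
                                  ev.classifier_label, ev.checklist_label)
                  if lab is not None]
        counts = pd.Series(labels).value_counts() if labels else pd.Series(dtype=int)
        agreeing = counts[counts >= 2]
        conflict = len(agreeing) > 1
        if conflict and prioritize_optic_lobe and ev.optic_lobe and \
                ev.classifier_label in agreeing.index:
            rows.append((ev.cluster, ev.classifier_label, "consensus", True))
        elif conflict:
            rows.append((ev.cluster, None, "unannotated", True))
        elif len(agreeing) == 1:
            rows.append((ev.cluster, agreeing.index[0], "consensus", False))
        elif len(labels) == 1:
            rows.append((ev.cluster, labels[0], "single-source", False))
        else:
            rows.append((ev.cluster, None, "unannotated", False))
    return pd.DataFrame(rows, columns=["cluster", "label", "tier", "conflict"]
                        ).set_index("cluster")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_reference_atlas(ds: Dataset, nm: NormalizedMatrix, clusters: pd.Series,
                          n_features: int = 500, top_k: int = 20,
                          source: str = "reference") -> ReferenceAtlas:
    """Build an atlas (centroids + markers + features) from a labelled dataset."""
    clusters = clusters.loc[nm.cells]
    feats = select_dropout_features(ds, n_features=n_features)
    cent = {}
    for cl, cells in clusters.groupby(clusters):
        idx = nm.cells.get_indexer(cells.index)
        cent[cl] = nm.values[:, idx].mean(axis=1)
    centroids = pd.DataFrame(cent, index=nm.genes).T
    markers = cluster_markers(nm, clusters, top_k=top_k)
    return ReferenceAtlas(
        centroids=centroids,
        top_markers={cl: top for cl, (top, _full) in markers.items()},
        full_markers={cl: full for cl, (_top, full) in markers.items()},
        features=list(feats),
        source=source,
    )


def annotate_clusters(ds: Dataset, nm: NormalizedMatrix, clusters: pd.Series,
                      atlas: ReferenceAtlas, threshold: float = 0.7,
                      min_shared: int = 13, top_k: int = 20,
                      classifier_labels: pd.Series | None = None,
                      prioritize_optic_lobe: bool = False) -> pd.DataFrame:
    """Run the evidence channels for every query cluster and consolidate."""
    clusters = clusters.loc[nm.cells]
    cell_map = map_cells(nm, atlas, threshold=threshold)
    markers = cluster_markers(nm, clusters, top_k=top_k)
    evidence = []
    for cl in pd.unique(clusters):
        cells = clusters.index[clusters == cl]
        mapped = cell_map.loc[cells].dropna()
        scmap_label, coverage = None, 0.0
        if len(mapped):
            counts = mapped.value_counts()
            coverage = counts.iloc[0] / len(mapped)
            if coverage > 0.5:
                scmap_label = counts.index[0]
        top, _full = markers[cl]
        m_label, m_shared, _tied = marker_overlap_map(
            top, atlas.top_markers, min_shared=min_shared,
            ref_full=atlas.full_markers)
        evidence.append(AnnotationEvidence(
            cluster=cl, scmap_label=scmap_label, scmap_coverage=coverage,
            marker_label=m_label, marker_shared=m_shared,
            classifier_label=(classifier_labels.get(cl)
                              if classifier_labels is not None else None),
        ))
    result = consolidate_annotations(evidence,
                                     prioritize_optic_lobe=prioritize_optic_lobe)
    detail = pd.DataFrame(
        [(e.cluster, e.scmap_label, e.scmap_coverage, e.marker_label,
          e.marker_shared) for e in evidence],
        columns=["cluster", "scmap_label", "scmap_coverage", "marker_label",
                 "marker_shared"],
    ).set_index("cluster")
    return result.join(detail)
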