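import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import tauaging as ta
from tauaging import annotate as an


# ---------------------------------------------------------------------------
# map_cell voting rule
# ---------------------------------------------------------------------------

def test_map_cell_two_votes_one_above_threshold():
    scores = {"cosine": [0.9, 0.1], "spearman": [0.8, 0.2],
              "pearson": [0.2, 0.6]}
    assert an.map_cell(scores) == 0


def test_map_cell_all_three_disagree():
    scores = {"cosine": [0.9, 0.0, 0.0], "spearman": [0.0, 0.9, 0.0],
              "pearson": [0.0, 0.0, 0.9]}
    assert an.map_cell(scores) is None


def test_map_cell_votes_below_threshold_unassigned():
    scores = {"cosine": [0.65, 0.1], "spearman": [0.69, 0.2],
              "pearson": [0.1, 0.75]}
    assert an.map_cell(scores) is None


def test_map_cell_tied_measure_abstains():
    scores = {"cosine": [0.8, 0.8], "spearman": [0.9, 0.1],
              "pearson": [0.85, 0.1]}
    # cosine abstains on the exact tie; spearman+pearson still concordant
    assert an.map_cell(scores) == 0
    only_tie = {"cosine": [0.8, 0.8], "spearman": [0.9, 0.1],
                "pearson": [0.1, 0.85]}
    assert an.map_cell(only_tie) is None


def test_map_cell_lower_threshold_is_monotone():
    rng = np.random.default_rng(0)
    for _ in range(50):
        scores = {m: rng.random(4) for m in ("cosine", "spearman", "pearson")}
        strict = an.map_cell(scores, threshold=0.7)
        loose = an.map_cell(scores, threshold=0.4)
        if strict is not None:
            assert loose == strict


# ---------------------------------------------------------------------------
# marker intersection mapping
# ---------------------------------------------------------------------------

def _tops(**kwargs):
    return dict(kwargs)


def test_marker_map_identical_list_full_share():
    top = [f"g{i}" for i in range(20)]
    ref, shared, tied = an.marker_overlap_map(top, _tops(R=top), min_shared=13)
    assert ref == "R" and shared == 20 and not tied


def test_marker_map_threshold_13_boundary():
    top = [f"g{i}" for i in range(20)]
    ref13 = top[:13] + [f"x{i}" for i in range(7)]
    ref12 = top[:12] + [f"x{i}" for i in range(8)]
    assert an.marker_overlap_map(top, _tops(R=ref13))[0] == "R"
    assert an.marker_overlap_map(top, _tops(R=ref12))[0] is None


def test_marker_map_jaccard_tiebreak():
    top = [f"g{i}" for i in range(20)]
    shared15 = top[:15]
    refA = shared15 + [f"a{i}" for i in range(5)]
    refB = shared15 + [f"b{i}" for i in range(5)]
    fullA = refA + [f"g{i}" for i in range(15, 20)]  # higher Jaccard with query
    fullB = refB + [f"zz{i}" for i in range(30)]
    ref, shared, tied = an.marker_overlap_map(
        top, _tops(A=refA, B=refB), min_shared=13,
        ref_full={"A": fullA, "B": fullB})
    assert ref == "A" and shared == 15 and not tied


def test_marker_map_empty_query():
    assert an.marker_overlap_map([], _tops(R=["g1"]))[0] is None


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------

def test_consolidation_tiers():
    ev = [
        an.AnnotationEvidence("q0", scmap_label="R", marker_label="R"),
        an.AnnotationEvidence("q1", classifier_label="S"),
        an.AnnotationEvidence("q2"),
        an.AnnotationEvidence("q3", scmap_label="R", marker_label="R",
                              classifier_label="T", checklist_label="T"),
    ]
    out = an.consolidate_annotations(ev)
    assert out.loc["q0", "label"] == "R" and out.loc["q0", "tier"] == "consensus"
    assert out.loc["q1", "label"] == "S" and out.loc["q1", "tier"] == "single-source"
    assert out.loc["q2", "label"] is None and out.loc["q2", "tier"] == "unannotated"
    # two disjoint agreeing pairs -> conflict
    assert out.loc["q3", "tier"] == "unannotated" and out.loc["q3", "conflict"]


def test_consolidation_optic_lobe_priority():
    ev = [an.AnnotationEvidence("q", scmap_label="R", marker_label="R",
                                classifier_label="T", checklist_label="T",
                                optic_lobe=True)]
    out = an.consolidate_annotations(ev, prioritize_optic_lobe=True)
    assert out.loc["q", "label"] == "T"


# ---------------------------------------------------------------------------
# dropout-feature selection
# ---------------------------------------------------------------------------

def test_dropout_features_prefer_planted_high_dropout_genes():
    """Genes given extra post-hoc zeroing rank above unperturbed genes whose
    observed mean expression is comparable."""
    rng = np.random.default_rng(1)
    n_genes, n_cells = 300, 400
    mu = np.exp(rng.normal(0.5, 1.0, size=n_genes))  # spread of expression
    counts = rng.poisson(mu[:, None], size=(n_genes, n_cells)).astype(float)
    well_expressed = np.flatnonzero((mu > 1.0) & (mu < 5.0))
    zeroed = rng.choice(well_expressed, 20, replace=False)
    mask = rng.random((20, n_cells)) < 0.6
    counts[zeroed] = counts[zeroed] * (~mask)
    ds = ta.Dataset(sp.csr_matrix(counts),
                    pd.Index([f"g{i}" for i in range(n_genes)]),
                    pd.Index([f"c{j}" for j in range(n_cells)]))
    ranked = an.select_dropout_features(ds, n_features=n_genes)
    pos = {g: i for i, g in enumerate(ranked)}
    mean_expr = counts.mean(axis=1)
    unperturbed = [i for i in range(n_genes) if i not in set(zeroed)]
    wins = 0
    for gi in zeroed:
        partner = min(unperturbed, key=lambda j: abs(mean_expr[j] - mean_expr[gi]))
        if pos[f"g{gi}"] < pos[f"g{partner}"]:
            wins += 1
    assert wins >= 18


def test_dropout_features_never_select_zero_dropout_first():
    rng = np.random.default_rng(2)
    counts = rng.poisson(1.0, size=(50, 100)).astype(float)
    counts[0] = 5.0  # gene detected everywhere: zero dropout
    ds = ta.Dataset(sp.csr_matrix(counts),
                    pd.Index([f"g{i}" for i in range(50)]),
                    pd.Index([f"c{j}" for j in range(100)]))
    feats = an.select_dropout_features(ds, n_features=30)
    assert "g0" not in feats


def test_dropout_features_length_capped_with_warning():
    counts = np.zeros((10, 20))
    counts[:4] = 1.0
    ds = ta.Dataset(sp.csr_matrix(counts),
                    pd.Index([f"g{i}" for i in range(10)]),
                    pd.Index([f"c{j}" for j in range(20)]))
    with pytest.warns(UserWarning, match="expressed genes"):
        feats = an.select_dropout_features(ds, n_features=8)
    assert len(feats) == 4


# ---------------------------------------------------------------------------
# self-annotation and similarity invariances
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def self_atlas():
    spec = ta.SimSpec(cells_per_cluster_per_library=40, n_regulons=5, seed=13)
    ds, _, _ = ta.simulate(spec)
    nm = ta.lognormalize(ds)
    atlas = an.build_reference_atlas(ds, nm, ds.meta["cluster"],
                                     source="self")
    return spec, ds, nm, atlas


def test_self_annotation_is_identity(self_atlas):
    spec, ds, nm, atlas = self_atlas
    # centroid self-similarity: each cluster centroid maps to itself with 1.0
    feats = atlas.features
    cent = atlas.centroids.loc[:, feats].to_numpy()
    sims = an.compute_similarities(cent, cent)
    for m in ("cosine", "pearson", "spearman"):
        np.testing.assert_allclose(np.diag(sims[m]), 1.0, atol=1e-10)
        assert (sims[m].argmax(axis=1) == np.arange(cent.shape[0])).all()
    # marker lists shared in full
    for cl, top in atlas.top_markers.items():
        ref, shared, _ = an.marker_overlap_map(top, atlas.top_markers,
                                               min_shared=13)
        if len(top) >= 13:
            assert ref == cl and shared == len(top)


def test_similarity_scale_and_monotone_invariance(self_atlas):
    _, _, nm, atlas = self_atlas
    feats = [f for f in atlas.features if f in nm.genes][:100]
    gi = nm.genes.get_indexer(pd.Index(feats))
    profiles = nm.values[gi, :5].T
    centroids = atlas.centroids.loc[:, feats].to_numpy()
    base = an.compute_similarities(profiles, centroids)
    scaled = an.compute_similarities(profiles * 3.7, centroids)
    np.testing.assert_allclose(base["cosine"], scaled["cosine"], atol=1e-12)
    mono = an.compute_similarities(np.exp(profiles), centroids)
    np.testing.assert_allclose(base["spearman"], mono["spearman"], atol=1e-12)


def test_atlas_round_trip_recovers_permutation(small_study, small_lognorm):
    spec, ds = small_study["spec"], small_study["ds"]
    ref_ds, perm = ta.simulate_reference_atlas(spec, perturb_sd=0.05)
    ref_nm = ta.lognormalize(ref_ds)
    atlas = an.build_reference_atlas(ref_ds, ref_nm, ref_ds.meta["cluster"])
    result = an.annotate_clusters(ds, small_lognorm, ds.meta["cluster"], atlas)
    correct = sum(result.loc[cl, "label"] == perm[cl] for cl in perm)
    assert correct >= 0.95 * len(perm)
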