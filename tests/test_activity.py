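import numpy as np
import pandas as pd
import pytest

import tauaging as ta
from tauaging import activity as ac
from tauaging.io import GeneSet
from tauaging.qc import NormalizedMatrix


def _nm(values, genes=None, cells=None, transform="lognorm"):
    values = np.asarray(values, dtype=float)
    genes = pd.Index(genes or [f"g{i}" for i in range(values.shape[0])])
    cells = pd.Index(cells or [f"c{j}" for j in range(values.shape[1])])
    return NormalizedMatrix(values, genes, cells, transform)


# ---------------------------------------------------------------------------
# mean activity
# ---------------------------------------------------------------------------

def test_mean_activity_singleton_equals_expression_row():
    nm = _nm([[1.0, 2.0], [3.0, 4.0]])
    act = ta.mean_activity(nm, [GeneSet("S", ["g1"])])
    np.testing.assert_allclose(act.values["S"], [3.0, 4.0])


def test_mean_activity_two_gene_average():
    nm = _nm([[2.0], [4.0], [9.0]])
    act = ta.mean_activity(nm, [GeneSet("S", ["g0", "g1"])])
    assert act.values["S"].iloc[0] == 3.0


def test_mean_activity_invariant_to_duplicate_members():
    nm = _nm([[2.0], [4.0]])
    a = ta.mean_activity(nm, [GeneSet("S", ["g0", "g1"])])
    b = ta.mean_activity(nm, [GeneSet("S", ["g0", "g1", "g1", "g0"])])
    np.testing.assert_allclose(a.values["S"], b.values["S"])


def test_mean_activity_missing_members_dropped_and_empty_warns():
    nm = _nm([[2.0], [4.0]])
    act = ta.mean_activity(nm, [GeneSet("S", ["g0", "nope"])])
    assert act.values["S"].iloc[0] == 2.0
    assert act.frac_present["S"] == 0.5
    with pytest.warns(UserWarning, match="no members"):
        act2 = ta.mean_activity(nm, [GeneSet("T", ["zz"])])
    assert np.isnan(act2.values["T"].iloc[0])


def test_mean_activity_linearity_over_disjoint_sets():
    rng = np.random.default_rng(0)
    nm = _nm(rng.random((10, 6)))
    a = ta.mean_activity(nm, [GeneSet("A", ["g0", "g1"]),
                              GeneSet("B", ["g2", "g3"]),
                              GeneSet("U", ["g0", "g1", "g2", "g3"])])
    np.testing.assert_allclose(
        a.values["U"], (a.values["A"] + a.values["B"]) / 2.0, atol=1e-12)


# ---------------------------------------------------------------------------
# AUC activity
# ---------------------------------------------------------------------------

def test_auc_brute_force_oracle_equivalence_both_modes():
    rng = np.random.default_rng(1)
    for _ in range(100):
        G, n = 30, 3
        vals = rng.random((G, n)) * (rng.random((G, n)) > 0.3)
        genes = [f"g{i}" for i in range(G)]
        nm = _nm(vals, genes=genes)
        members = rng.choice(G, size=3, replace=False)
        s = GeneSet("S", [genes[i] for i in members])
        k_max = int(np.floor(0.2 * G))
        for mode in ("A", "B"):
            act = ta.auc_activity(nm, [s], top_fraction=0.2, normalization=mode)
            for j in range(n):
                rec = ac.auc_recovery_curve(vals[:, j], members, k_max)
                expected = rec.sum() / ac._auc_denominator(3, k_max, mode)
                assert act.values.iloc[j, 0] == pytest.approx(expected, abs=1e-14)


def test_auc_best_case_closed_forms():
    G = 30
    vals = np.zeros((G, 1))
    vals[:6, 0] = np.arange(6, 0, -1)
    genes = [f"g{i}" for i in range(G)]
    nm = _nm(vals, genes=genes)
    s = GeneSet("S", genes[:6])  # exactly the top k_max = 6 genes
    a = ta.auc_activity(nm, [s], top_fraction=0.2, normalization="A")
    b = ta.auc_activity(nm, [s], top_fraction=0.2, normalization="B")
    assert a.values.iloc[0, 0] == pytest.approx((6 + 1) / (2 * 6))
    assert b.values.iloc[0, 0] == pytest.approx(1.0)


def test_auc_set_outside_top_window_is_zero():
    G = 40
    vals = np.arange(G, 0, -1, dtype=float)[:, None]
    genes = [f"g{i}" for i in range(G)]
    nm = _nm(vals, genes=genes)
    s = GeneSet("S", genes[-3:])  # lowest-ranked genes
    act = ta.auc_activity(nm, [s], top_fraction=0.1)
    assert act.values.iloc[0, 0] == 0.0


def test_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(2)
    vals = rng.random((50, 4))
    genes = [f"g{i}" for i in range(50)]
    s = GeneSet("S", [genes[i] for i in rng.choice(50, 5, replace=False)])
    a = ta.auc_activity(_nm(vals, genes=genes), [s])
    b = ta.auc_activity(_nm(np.exp(3 * vals), genes=genes), [s])
    np.testing.assert_allclose(a.values["S"], b.values["S"], atol=1e-14)


def test_auc_enlarging_window_never_decreases_contained_set():
    rng = np.random.default_rng(3)
    G = 60
    vals = rng.random((G, 3))
    genes = [f"g{i}" for i in range(G)]
    nm = _nm(vals, genes=genes)
    for j in range(3):
        top = np.argsort(-vals[:, j])[:3]
        s = GeneSet("S", [genes[i] for i in top])
        small = ta.auc_activity(nm, [s], top_fraction=0.1,
                                normalization="A").values["S"].iloc[j]
        big = ta.auc_activity(nm, [s], top_fraction=0.3,
                              normalization="A").values["S"].iloc[j]
        assert big >= small - 1e-12


def test_auc_values_in_unit_interval(small_lognorm, small_study):
    act = ta.auc_activity(small_lognorm, small_study["regulons"][:5])
    v = act.values.to_numpy()
    assert np.nanmin(v) >= 0.0 and np.nanmax(v) <= 1.0


def test_auc_zero_window_is_error():
    nm = _nm(np.random.default_rng(4).random((10, 2)))
    with pytest.raises(ValueError, match="top_fraction"):
        ta.auc_activity(nm, [GeneSet("S", ["g0"])], top_fraction=0.01)


# ---------------------------------------------------------------------------
# cluster-level log2FC of activity
# ---------------------------------------------------------------------------

def _meta(cells, cluster, genotype, age=10):
    return pd.DataFrame({"cluster": cluster, "genotype": genotype, "age": age},
                        index=cells)


def test_cluster_activity_lfc_ratio_of_means():
    act = ta.mean_activity(_nm([[2.0, 2.0, 1.0, 1.0]]), [GeneSet("S", ["g0"])])
    meta = _meta(act.cells, "A", ["tau", "tau", "control", "control"])
    lfc = ta.cluster_activity_lfc(act, meta)
    assert lfc.loc["A", "S"] == pytest.approx(1.0)
    equal = ta.mean_activity(_nm([[3.0, 3.0, 3.0, 3.0]]), [GeneSet("S", ["g0"])])
    assert ta.cluster_activity_lfc(equal, meta).loc["A", "S"] == 0.0


def test_cluster_activity_lfc_rejects_zscore():
    act = ta.mean_activity(_nm([[1.0, 2.0]]), [GeneSet("S", ["g0"])])
    act.method = "zscore"
    with pytest.raises(ValueError):
        ta.cluster_activity_lfc(act, _meta(act.cells, "A", ["tau", "control"]))


def test_planted_regulon_activation_recovered(small_study, small_lognorm):
    act = ta.mean_activity(small_lognorm, small_study["regulons"])
    lfc = ta.cluster_activity_lfc(act, small_study["ds"].meta)
    truth = small_study["truth"]
    affected = lfc.loc[truth.tau_affected_clusters, "Rel-like"]
    others = lfc.drop(index=truth.tau_affected_clusters)["Rel-like"]
    assert affected.min() > 0.25  # activation clearly recovered
    assert others.abs().max() < 0.1


# ---------------------------------------------------------------------------
# differential activity LRT
# ---------------------------------------------------------------------------

def test_differential_activity_matches_two_model_refit_oracle(small_study,
                                                              small_lognorm):
    act = ta.mean_activity(small_lognorm, small_study["regulons"][:3])
    meta = small_study["ds"].meta
    out = ta.differential_activity(act, meta)
    row = out[(out["cluster"] == "KC-ab") & (out["set"] == "Rel-like")].iloc[0]
    sub = meta[meta["cluster"] == "KC-ab"]
    y = act.values.loc[sub.index, "Rel-like"].to_numpy()
    geno = (sub["genotype"] == "tau").to_numpy(float)
    age = sub["age"].to_numpy(float)
    n = len(y)
    Xf = np.column_stack([np.ones(n), age, geno])
    Xr = Xf[:, :2]
    rss = lambda X: float(((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum())
    assert row["chi2"] == pytest.approx(n * np.log(rss(Xr) / rss(Xf)), rel=1e-9)


def test_differential_activity_permutation_null_calibrated(small_study,
                                                           small_lognorm):
    rng = np.random.default_rng(5)
    act = ta.mean_activity(small_lognorm, small_study["regulons"])
    meta = small_study["ds"].meta.copy()
    meta["genotype"] = rng.permutation(meta["genotype"].to_numpy())
    out = ta.differential_activity(act, meta)
    rate = (out["p"] < 0.05).mean()
    n = out["p"].notna().sum()
    # sets overlap in members, so tests correlate; generous binomial-ish band
    assert 0.01 <= rate <= 0.10, f"null rejection {rate} over {n} tests"


def test_planted_activation_significant(small_study, small_lognorm):
    act = ta.mean_activity(small_lognorm, small_study["regulons"])
    out = ta.differential_activity(act, small_study["ds"].meta)
    rel = out[out["set"] == "Rel-like"].set_index("cluster")
    truth = small_study["truth"]
    assert (rel.loc[truth.tau_affected_clusters, "padj"] < 0.05).all()
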