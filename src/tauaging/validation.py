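"""Planted-truth validation experiments.

Each experiment builds synthetic data with the generator, runs the relevant
pipeline stage, and measures recovery of the planted ground truth or the
calibration of a null.  They are consumed by the test suite and by the
repository's acceptance script; problem sizes are desk-scale (hundreds of
cells per group, 1,000-2,000 genes) so a full run completes in minutes.
"""

from __future__ import annotations

import hashlib
from itertools import combinations

import numpy as np
import pandas as pd

from . import abundance as ab
from . import activity as ac
from . import annotate as an
from . import crossspecies as xs
from . import de as de_mod
from . import qc as qc_mod
from . import vulnerability as vu
from importlib import import_module

sim = import_module("tauaging.simulate")

__all__ = [
    "subseed",
    "hurdle_null_calibration",
    "de_recovery",
    "overlap_recovery",
    "abundance_recovery",
    "abundance_null_calibration",
    "anchor_properties",
    "size_factor_oracle",
    "auc_oracle",
    "enet_oracles",
    "annotation_roundtrip",
    "hypergeom_oracle",
    "xspecies_matching",
    "pipeline_determinism",
]


def subseed(seed: int, label: str) -> int:
    """Stable derived seed below 2^31 for one experiment."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# hurdle DE
# ---------------------------------------------------------------------------

def _two_group_spec(seed: int, n_genes: int, n_tau: int, cells_per_group: int,
                    libsize_sigma: float = 0.35):
    return sim.SimSpec(
        clusters=["neuron"], anchor_clusters=[],
        tau_affected_clusters=["neuron"] if n_tau else [],
        libraries=[("control", 10, 0), ("tau", 10, 0)],
        cells_per_cluster_per_library=cells_per_group,
        n_genes=n_genes, n_aging_genes=0, n_tau_genes=max(n_tau, 1),
        rel_activation=1.0, n_regulons=2, vulnerability_beta=0.0,
        abundance_noise_sd=0.0, libsize_sigma=libsize_sigma, seed=seed,
    )


def hurdle_null_calibration(seed: int = 0, n_genes: int = 2000,
                            cells_per_group: int = 150) -> float:
    """Rejection rate of the hurdle LRT at p < 0.05 on group-null NB data.

    300 cells in two equal groups with no planted group effect and equal
    cell depths (the clean NB null: lognormal depth variation makes the
    linear-CDR detection model mildly misspecified, which is a documented
    limitation rather than a calibration property).  The rate should sit
    in the binomial band around the nominal 0.05.
    """
    spec = _two_group_spec(seed, n_genes, n_tau=0,
                           cells_per_group=cells_per_group, libsize_sigma=0.0)
    ds, _, _ = sim.simulate(spec)
    nm = qc_mod.lognormalize(ds)
    design = de_mod.ContrastDesign("genotype", ("tau", "control"), ("cdr",))
    tab = de_mod.de_test(nm, ds.meta, design)
    return float((tab["p_val"] < 0.05).mean())


def de_recovery(seed: int = 0, n_genes: int = 2000,
                cells_per_group: int = 300):
    """Sensitivity and empirical FDR with |log2FC| = 1 planted in 10% of genes."""
    n_tau = n_genes // 10
    spec = _two_group_spec(seed, n_genes, n_tau=n_tau,
                           cells_per_group=cells_per_group)
    ds, truth, _ = sim.simulate(spec)
    nm = qc_mod.lognormalize(ds)
    design = de_mod.ContrastDesign("genotype", ("tau", "control"), ("cdr",))
    tab = de_mod.de_test(nm, ds.meta, design)
    sig = tab[tab["significant"]]
    planted = set(truth.tau_genes)
    tp = int(sig["gene"].isin(planted).sum())
    sensitivity = tp / len(planted)
    fdr = (len(sig) - tp) / max(len(sig), 1)
    return float(sensitivity), float(fdr)


def overlap_recovery(seed: int = 0, n_seeds: int = 10,
                     cells_per_cluster_per_library: int = 120):
    """Mean estimated tau/aging overlap with 0.93 planted, across seeds.

    Six clusters with a single tau-affected cluster and no regulon
    activation: the union-based estimator is then diluted only by one
    cluster family's false discoveries, matching the statistic's behaviour
    at full scale.
    """
    clusters = ["KC-ab", "PN", "L1-5", "Mi1", "Ensheathing-glia", "Cortex-glia"]
    estimates = []
    for i in range(n_seeds):
        spec = sim.SimSpec(
            clusters=clusters,
            anchor_clusters=["Ensheathing-glia", "Cortex-glia"],
            tau_affected_clusters=["KC-ab"],
            cells_per_cluster_per_library=cells_per_cluster_per_library,
            rel_activation=1.0, n_regulons=2,
            tau_aging_overlap_frac=0.93,
            seed=subseed(seed, f"overlap{i}"),
        )
        ds, _, _ = sim.simulate(spec)
        nm = qc_mod.lognormalize(ds)
        tau_sets = de_mod.significant_gene_sets(
            de_mod.de_test(nm, ds.meta, de_mod.tau_design()))
        aging_sets: dict = {}
        for pair in [(1, 10), (10, 20)]:
            t = de_mod.de_test(nm, ds.meta, de_mod.aging_design(pair))
            for cl, genes in de_mod.significant_gene_sets(t).items():
                aging_sets.setdefault(cl, set()).update(genes)
        frac, _ = de_mod.overlap_statistic(tau_sets, aging_sets)
        estimates.append(frac if frac is not None else np.nan)
    return float(np.nanmean(estimates)), [float(e) for e in estimates]


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------

def abundance_recovery(seed: int = 0, cells_per_cluster_per_library: int = 150):
    """Recovery of planted per-cluster log2FC in {-1, 0, +0.5}.

    Uses the replicated single-age design (3 libraries per genotype) with a
    modest planted mass so the compositional renormalization stays small;
    returns (max abs estimation error over planted clusters, sensitivity
    for the declining clusters at padj < 0.05).
    """
    planted = {"KC-ab": -1.0, "KC-g": -1.0, "PN": 0.5}
    spec = sim.SimSpec(
        libraries=sim.replication_libraries(3),
        cells_per_cluster_per_library=cells_per_cluster_per_library,
        abundance_log2fc=planted, n_regulons=2,
        seed=subseed(seed, "abundance"),
    )
    ds, truth, _ = sim.simulate(spec)
    tbl = ab.count_cells(ds.meta)
    rec = ab.fit_abundance(tbl, design="genotype")
    err = max(abs(rec.loc[cl, "log2FC"] - truth.abundance_log2fc[cl])
              for cl in rec.index)
    declining = [cl for cl, v in truth.abundance_log2fc.items() if v < 0]
    sens = float(np.mean([rec.loc[cl, "padj"] < 0.05 for cl in declining]))
    return float(err), sens


def abundance_null_calibration(seed: int = 0, n_clusters: int = 100,
                               n_datasets: int = 2) -> float:
    """Genotype-permutation null: Wald rejection rate at p < 0.05.

    Simulated multi-cluster count tables (replicated single-age design, no
    planted abundance change) with genotype labels permuted across
    libraries; pools ~200 cluster-level tests.
    """
    rng = np.random.default_rng(subseed(seed, "abnull"))
    pvals = []
    for r in range(n_datasets):
        spec = sim.SimSpec(
            clusters=[f"cl{i:03d}" for i in range(n_clusters)],
            anchor_clusters=[], tau_affected_clusters=[],
            n_marker_genes=0, n_genes=60, n_mito_genes=0,
            n_aging_genes=0, n_tau_genes=1, n_regulons=1, regulon_size=5,
            rel_activation=1.0, vulnerability_beta=0.0,
            abundance_noise_sd=0.0, cells_per_cluster_per_library=40,
            libraries=sim.replication_libraries(3),
            seed=subseed(seed, f"abnull{r}"),
        )
        ds, _, _ = sim.simulate(spec)
        meta = ds.meta.copy()
        libs = list(meta["library"].unique())
        genos = [meta.loc[meta["library"] == l, "genotype"].iloc[0]
                 for l in libs]
        perm = dict(zip(libs, rng.permutation(genos)))
        meta["genotype"] = meta["library"].map(perm)
        rec = ab.fit_abundance(ab.count_cells(meta), design="genotype")
        pvals.append(rec["p"].to_numpy())
    p = np.concatenate(pvals)
    return float(np.nanmean(p < 0.05))


def anchor_properties(seed: int = 0, n_instances: int = 100):
    """Exact anchoring properties on random log2FC vectors.

    Returns (fraction of anchors whose range contains zero — must be 1 —
    and fraction of instances where widening the anchor set never narrows
    any range — must be 1).
    """
    rng = np.random.default_rng(subseed(seed, "anchor"))
    cover = mono = 0
    for _ in range(n_instances):
        k = int(rng.integers(5, 15))
        rec = pd.DataFrame({"log2FC": rng.normal(scale=1.0, size=k)},
                           index=[f"c{i}" for i in range(k)])
        n_anchor = int(rng.integers(1, k // 2 + 1))
        anchors = [f"c{i}" for i in rng.choice(k, n_anchor, replace=False)]
        out = ab.anchor_adjust(rec, anchors)
        ok = all(out.loc[a, "min_log2FC"] <= 0.0 <= out.loc[a, "max_log2FC"]
                 for a in anchors)
        cover += ok
        extra = [c for c in rec.index if c not in anchors][:2]
        wide = ab.anchor_adjust(rec, anchors + extra)
        mono += bool((wide["min_log2FC"] <= out["min_log2FC"] + 1e-12).all()
                     and (wide["max_log2FC"] >= out["max_log2FC"] - 1e-12).all())
    return cover / n_instances, mono / n_instances


def size_factor_oracle(seed: int = 0):
    """Scaled-library oracle: factor ratio error and median normalized ratio."""
    rng = np.random.default_rng(subseed(seed, "sf"))
    base = rng.integers(10, 500, size=25).astype(float)
    c = 3.0
    counts = pd.DataFrame({"l1": base, "l2": c * base})
    lm = pd.DataFrame({"genotype": ["control", "tau"], "age": [10, 10]},
                      index=counts.columns)
    s = ab.size_factors(ab.ClusterCountTable(counts, lm))
    ratio_err = abs(s["l2"] / s["l1"] - c)
    norm = counts.to_numpy() / s.to_numpy()
    median_ratio = float(np.median(norm[:, 1] / norm[:, 0]))
    return float(ratio_err), median_ratio


# ---------------------------------------------------------------------------
# activity / elastic net oracles
# ---------------------------------------------------------------------------

def auc_oracle(seed: int = 0, n_instances: int = 100) -> float:
    """Max |vectorized - brute force| AUC over random toys, both modes."""
    rng = np.random.default_rng(subseed(seed, "auc"))
    from .io import GeneSet
    worst = 0.0
    for _ in range(n_instances):
        G, n = 30, 3
        vals = rng.random((G, n)) * (rng.random((G, n)) > 0.3)
        genes = [f"g{i}" for i in range(G)]
        nm = qc_mod.NormalizedMatrix(vals, pd.Index(genes),
                                     pd.Index([f"c{j}" for j in range(n)]),
                                     "lognorm")
        members = rng.choice(G, size=3, replace=False)
        s = GeneSet("S", [genes[i] for i in members])
        k_max = int(np.floor(0.2 * G))
        for mode in ("A", "B"):
            act = ac.auc_activity(nm, [s], top_fraction=0.2, normalization=mode)
            for j in range(n):
                rec = ac.auc_recovery_curve(vals[:, j], members, k_max)
                expected = rec.sum() / ac._auc_denominator(3, k_max, mode)
                worst = max(worst, abs(act.values.iloc[j, 0] - expected))
    return float(worst)


def _toy_design(n, p, seed, beta=(-1.0,), noise=0.1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"s{j}" for j in range(p)])
    X = (X - X.mean()) / X.std(ddof=0)
    y = pd.Series(np.zeros(n))
    for j, b in enumerate(beta):
        y = y + b * X[f"s{j}"]
    y = y + noise * rng.normal(size=n)
    return vu.VulnerabilityDesign(X=X, y=y, column_means=X.mean(),
                                  column_sds=X.std(ddof=0))


def enet_oracles(seed: int = 0):
    """Closed-form agreement and planted-predictor ranking for the elastic net.

    Returns (max |coef - least squares| at lambda=0, |coef - analytic
    soft-threshold| for the univariate lasso, fraction of 100 seeded
    replicates ranking the informative predictor first).
    """
    base = subseed(seed, "enet")
    d = _toy_design(12, 5, base)
    m = vu.enet_fit(d, alpha=0.5, lam=0.0, tol=1e-10)
    A = np.column_stack([np.ones(12), d.X.to_numpy()])
    beta, *_ = np.linalg.lstsq(A, d.y.to_numpy(), rcond=None)
    ls_err = float(np.abs(np.r_[m.intercept, m.coef.to_numpy()] - beta).max())

    d1 = _toy_design(25, 1, base + 1, beta=(-0.8,), noise=0.2)
    x = d1.X.to_numpy()[:, 0]
    y = d1.y.to_numpy()
    lam = 0.15
    m1 = vu.enet_fit(d1, alpha=1.0, lam=lam, tol=1e-12)
    xc, yc = x - x.mean(), y - y.mean()
    rho = (xc @ yc) / len(y)
    st = np.sign(rho) * max(abs(rho) - lam, 0.0) / ((xc @ xc) / len(y))
    st_err = float(abs(m1.coef.iloc[0] - st))

    wins = 0
    for i in range(100):
        d3 = _toy_design(8, 40, subseed(seed, f"rank{i}"), beta=(-1.0,),
                         noise=0.1)
        ranked = vu.rank_predictors(vu.enet_fit(d3, alpha=0.5, lam=0.1))
        if len(ranked) and ranked.index[0] == "s0":
            wins += 1
    return ls_err, st_err, wins / 100


# ---------------------------------------------------------------------------
# annotation / cross-species round trips
# ---------------------------------------------------------------------------

def annotation_roundtrip(seed: int = 0,
                         cells_per_cluster_per_library: int = 60) -> float:
    """Fraction of clusters whose consensus label matches the planted permutation."""
    spec = sim.SimSpec(
        cells_per_cluster_per_library=cells_per_cluster_per_library,
        n_regulons=2, seed=subseed(seed, "annot"))
    ds, _, _ = sim.simulate(spec)
    ref_ds, perm = sim.simulate_reference_atlas(spec, perturb_sd=0.05)
    nm = qc_mod.lognormalize(ds)
    ref_nm = qc_mod.lognormalize(ref_ds)
    atlas = an.build_reference_atlas(ref_ds, ref_nm, ref_ds.meta["cluster"])
    result = an.annotate_clusters(ds, nm, ds.meta["cluster"], atlas)
    correct = sum(result.loc[cl, "label"] == perm[cl] for cl in perm)
    return correct / len(perm)


def xspecies_matching(seed: int = 0,
                      cells_per_cluster_per_library: int = 60) -> float:
    """Fraction of clusters whose correspondence row-argmax is the planted match."""
    import warnings

    spec = sim.SimSpec(
        cells_per_cluster_per_library=cells_per_cluster_per_library,
        n_regulons=2, seed=subseed(seed, "xsp"))
    ds, _, _ = sim.simulate(spec)
    ref_ds, perm = sim.simulate_reference_atlas(spec, perturb_sd=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = qc_mod.scale_genes(qc_mod.lognormalize(ds))
        zr = qc_mod.scale_genes(qc_mod.lognormalize(ref_ds))
    pa = xs.cluster_mean_profiles(z, ds.meta["cluster"])
    pb = xs.cluster_mean_profiles(zr, ref_ds.meta["cluster"])
    mat, _, _ = xs.correspondence(pa, pb)
    hits = sum(mat.loc[cl].idxmax() == perm[cl] for cl in perm)
    return hits / len(perm)


def hypergeom_oracle(seed: int = 0, n_instances: int = 200):
    """Exact agreement with exhaustive enumeration; plus the worked case.

    Returns (max |p - enumeration| over random small universes, p for the
    |U|=10, |A|=4, |B|=5, overlap=4 case).
    """
    rng = np.random.default_rng(subseed(seed, "hyper"))
    worst = 0.0
    for _ in range(n_instances):
        n_u = int(rng.integers(5, 13))
        universe = list(range(n_u))
        n_a = int(rng.integers(1, n_u + 1))
        n_b = int(rng.integers(1, n_u + 1))
        A = set(rng.choice(n_u, n_a, replace=False).tolist())
        B = set(rng.choice(n_u, n_b, replace=False).tolist())
        k, p = xs.overlap_test(A, B, universe)
        total = hits = 0
        for draw in combinations(universe, n_b):
            total += 1
            if len(A & set(draw)) >= k:
                hits += 1
        worst = max(worst, abs(p - hits / total))
    U = [f"u{i}" for i in range(10)]
    _, worked = xs.overlap_test(U[:4], U[:5], U)
    return float(worst), float(worked)


# ---------------------------------------------------------------------------
# end-to-end determinism
# ---------------------------------------------------------------------------

def pipeline_determinism(seed: int = 0, out_root=None) -> bool:
    """Run the full stage list twice with one seed; files must be byte-identical."""
    import hashlib as _h
    import tempfile
    from pathlib import Path

    from .pipeline import default_config, run_pipeline

    cfg = default_config()
    cfg["seed"] = subseed(seed, "determinism")
    cfg["simulate"].update({"cells_per_cluster_per_library": 25,
                            "n_regulons": 12})
    cfg["vulnerability"].update({"repeats": 2, "n_alpha": 3, "n_lambda": 6})

    def digest(d):
        return {str(p.relative_to(d)): _h.md5(p.read_bytes()).hexdigest()
                for p in sorted(Path(d).rglob("*")) if p.is_file()}

    with tempfile.TemporaryDirectory(dir=out_root) as tmp:
        run_pipeline(cfg, Path(tmp) / "a")
        run_pipeline(cfg, Path(tmp) / "b")
        return digest(Path(tmp) / "a") == digest(Path(tmp) / "b")
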