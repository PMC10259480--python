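"""Synthetic single-cell data with planted ground truth.

The generator emulates the longitudinal fly-brain study design: two
genotypes (control, tau) sampled at 1, 10 and 20 days (one library per
condition), plus an optional replicated single-age design.  It plants, and
records as ground truth,

* per-cluster abundance changes in tau animals, coupled negatively to the
  activity of one immune-like regulon (log2FC = -beta * activity + noise)
  with a reference class of anchor clusters whose change is exactly zero;
* aging-responsive genes, changing as a geometric progression across ages
  in every cluster, and tau-responsive genes, changing only in a
  "polarized" subset of clusters, with a controlled fraction of the tau
  set drawn from the aging set;
* regulon gene sets, one of which carries genotype-by-cluster activation.

Counts are negative binomial around cluster-gene means (gamma base means,
cluster marker structure, lognormal cell depth); dropout arises from NB
zeros alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import Dataset, GeneSet

__all__ = [
    "SimSpec",
    "GroundTruth",
    "simulate",
    "simulate_reference_atlas",
    "simulate_ortholog_table",
    "default_clusters",
]

NEURON_CLUSTERS = ["KC-ab", "KC-g", "PN", "L1-5", "Mi1", "T4-T5", "Dm-like", "NE"]
GLIA_CLUSTERS = ["Ensheathing-glia", "Astrocyte-like", "Cortex-glia"]
OTHER_CLUSTERS = ["Hemocyte"]


def default_clusters() -> list[str]:
    """Desk-scale cluster panel: 8 neuronal (2 Kenyon-cell-like), 3 glial, 1 hemocyte."""
    return NEURON_CLUSTERS + GLIA_CLUSTERS + OTHER_CLUSTERS


def _default_libraries() -> list[tuple]:
    return [(g, a, 0) for g in ("control", "tau") for a in (1, 10, 20)]


def replication_libraries(n_replicates: int = 3, age: int = 10) -> list[tuple]:
    """The replicated single-age design: n replicates per genotype at one age."""
    return [(g, age, r) for g in ("control", "tau") for r in range(n_replicates)]


@dataclass
class SimSpec:
    """Parameters of the synthetic study.

    Defaults are the desk-scale study conditions: 12 clusters, 1,000 genes,
    six libraries (2 genotypes x 3 ages) of ~1,800 cells each, 183 regulons,
    150 aging-responsive and 100 tau-responsive genes with 93% of the tau
    set shared with the aging set, planted effect |log2FC| = 1, and
    abundance decline coupled to the first (immune-like) regulon's activity
    with slope ``vulnerability_beta``.
    """

    n_genes: int = 1000
    clusters: list[str] = field(default_factory=default_clusters)
    cells_per_cluster_per_library: int = 150
    libraries: list[tuple] = field(default_factory=_default_libraries)
    baseline_shape: float = 0.3
    baseline_rate: float = 0.15
    libsize_sigma: float = 0.35
    dispersion: float = 10.0  # median NB size; per-gene sizes are lognormal around it
    dispersion_sigma: float = 0.5
    n_marker_genes: int = 25  # per cluster, disjoint, upweighted
    marker_boost: float = 8.0
    cluster_jitter_sd: float = 0.15
    n_mito_genes: int = 10
    n_aging_genes: int = 150
    n_tau_genes: int = 100
    tau_aging_overlap_frac: float = 0.93
    tau_affected_clusters: list[str] = field(
        default_factory=lambda: ["KC-ab", "KC-g", "PN", "L1-5", "Astrocyte-like"]
    )
    effect_log2fc: float = 1.0
    n_regulons: int = 183
    regulon_size: int = 15
    de_gene_min_mean: float = 0.25  # planted DE / regulon genes drawn from expressed genes
    rel_activation: float = 2.0  # tau-genotype multiplier on the immune regulon
    vulnerability_beta: float = 1.5
    abundance_noise_sd: float = 0.1
    anchor_clusters: list[str] = field(
        default_factory=lambda: GLIA_CLUSTERS + OTHER_CLUSTERS
    )
    abundance_log2fc: dict | None = None  # explicit per-cluster override
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_aging_overlap_frac <= 1.0:
            raise ValueError("tau_aging_overlap_frac must lie in [0, 1]")
        for name in ("n_genes", "cells_per_cluster_per_library", "n_regulons"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.tau_affected_clusters) - set(self.clusters)
        if unknown:
            raise ValueError(f"unknown tau_affected_clusters: {sorted(unknown)}")
        unknown = set(self.anchor_clusters) - set(self.clusters)
        if unknown:
            raise ValueError(f"unknown anchor_clusters: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Record of every planted effect of one simulation."""

    abundance_log2fc: dict  # cluster -> planted log2FC (0 for anchors)
    regulon_activity: dict  # cluster -> planted activity of the immune regulon
    aging_genes: dict  # gene -> direction (+1 / -1)
    tau_genes: dict  # gene -> direction
    tau_shared: set  # tau genes drawn from the aging set
    tau_unique: set
    tau_affected_clusters: list
    anchor_clusters: list
    vulnerability_beta: float
    seed: int


# ---------------------------------------------------------------------------
# structural parameters (shared between source data and reference atlas)
# ---------------------------------------------------------------------------

def _gene_names(spec: SimSpec) -> pd.Index:
    names = [f"mt:g{i:04d}" for i in range(spec.n_mito_genes)]
    names += [f"g{i:04d}" for i in range(spec.n_mito_genes, spec.n_genes)]
    return pd.Index(names)


def _structure(spec: SimSpec):
    """Deterministic structural draw: base means, markers, regulons, truth.

    Uses its own RNG stream so the reference atlas can share the structure
    while drawing independent sampling noise.
    """
    rng = np.random.default_rng((int(spec.seed) * 2654435761) % (2**31 - 1))
    genes = _gene_names(spec)
    K = len(spec.clusters)
    G = spec.n_genes

    base = rng.gamma(spec.baseline_shape, 1.0 / spec.baseline_rate, size=G)
    base = np.maximum(base, 1e-3)
    size = np.exp(rng.normal(np.log(spec.dispersion), spec.dispersion_sigma, size=G))

    # disjoint marker blocks give each cluster an identity
    marker = np.ones((K, G))
    order = rng.permutation(G)
    pos = 0
    marker_sets = {}
    for k, cl in enumerate(spec.clusters):
        take = order[pos:pos + spec.n_marker_genes]
        pos += spec.n_marker_genes
        marker[k, take] = spec.marker_boost
        marker_sets[cl] = [genes[i] for i in take]
    jitter = np.exp(rng.normal(0.0, spec.cluster_jitter_sd, size=(K, G)))
    cluster_means = base[None, :] * marker * jitter  # K × G

    # planted DE genes drawn outside the marker blocks, from expressed genes
    # (base mean above de_gene_min_mean) so planted effects are observable
    non_marker = [i for i in order[pos:] if base[i] >= spec.de_gene_min_mean]
    rng.shuffle(non_marker)
    need = spec.n_aging_genes + spec.n_tau_genes + spec.regulon_size
    if need > len(non_marker):
        raise ValueError("requested DE genes exceed available expressed non-marker genes")
    aging_idx = non_marker[: spec.n_aging_genes]
    n_shared = int(round(spec.tau_aging_overlap_frac * spec.n_tau_genes))
    n_shared = min(n_shared, spec.n_aging_genes)
    shared_idx = list(rng.choice(aging_idx, size=n_shared, replace=False))
    pool = [i for i in non_marker[spec.n_aging_genes:]]
    unique_idx = pool[: spec.n_tau_genes - n_shared]
    tau_idx = shared_idx + unique_idx

    # directions are assigned mass-balanced (greedy) so the planted effects
    # leave total cellular mRNA content unchanged: per-cell normalization
    # then shifts only the planted genes, not the rest through closure
    def _balanced_directions(idx, effect):
        up, down = 2.0 ** effect - 1.0, 2.0 ** (-effect) - 1.0
        imbalance = 0.0
        dirs = {}
        for i in idx:
            d = 1 if imbalance <= 0 else -1
            dirs[int(i)] = d
            imbalance += base[i] * (up if d == 1 else down)
        return dirs

    aging_dir = _balanced_directions(aging_idx, spec.effect_log2fc)
    tau_dir = _balanced_directions(tau_idx, spec.effect_log2fc)

    # regulons: the first is the immune-like (Rel-like) regulon with planted
    # per-cluster activity; the rest are inert random sets
    used = set(tau_idx) | set(aging_idx)
    rel_members = [i for i in non_marker if i not in used][: spec.regulon_size]
    regulons = [GeneSet(name="Rel-like", genes=[genes[i] for i in rel_members],
                        description="immune-like regulon (planted)")]
    for r in range(1, spec.n_regulons):
        members = rng.choice(G, size=spec.regulon_size, replace=False)
        regulons.append(GeneSet(name=f"regulon_{r:03d}",
                                genes=[genes[i] for i in members],
                                description="inert regulon"))

    # planted immune-regulon activity per cluster: 0 at anchors, spread over
    # non-anchors with the Kenyon-cell-like clusters most active
    activity = {}
    non_anchor = [c for c in spec.clusters if c not in spec.anchor_clusters]
    levels = np.linspace(0.2, 1.0, num=len(non_anchor))
    ordered = sorted(non_anchor, key=lambda c: (not c.startswith("KC"), c))
    for c, a in zip(ordered, levels[::-1]):
        activity[c] = float(a)
    for c in spec.anchor_clusters:
        activity[c] = 0.0

    # planted abundance change: explicit override, else -beta*activity + noise
    abundance = {}
    for c in spec.clusters:
        if c in spec.anchor_clusters:
            abundance[c] = 0.0
        elif spec.abundance_log2fc is not None:
            abundance[c] = float(spec.abundance_log2fc.get(c, 0.0))
        else:
            noise = rng.normal(0.0, spec.abundance_noise_sd)
            abundance[c] = float(-spec.vulnerability_beta * activity[c] + noise)

    base_weights = np.exp(rng.normal(0.0, 0.25, size=K))
    base_weights /= base_weights.sum()

    return {
        "genes": genes,
        "cluster_means": cluster_means,
        "size": size,
        "marker_sets": marker_sets,
        "aging_dir": aging_dir,
        "tau_dir": tau_dir,
        "shared_idx": set(int(i) for i in shared_idx),
        "unique_idx": set(int(i) for i in unique_idx),
        "rel_members": rel_members,
        "regulons": regulons,
        "activity": activity,
        "abundance": abundance,
        "base_weights": base_weights,
    }


_AGE_STEP = {1: 0, 10: 1, 20: 2}


def _condition_means(spec: SimSpec, st: dict, cluster_i: int, genotype: str,
                     age: int) -> np.ndarray:
    """Expected per-gene counts for one (cluster, genotype, age) condition."""
    cl = spec.clusters[cluster_i]
    mu = st["cluster_means"][cluster_i].copy()
    step = _AGE_STEP.get(age)
    if step is None:
        raise ValueError(f"unsupported age {age}; expected one of 1/10/20 days")
    if step:
        # geometric progression: each age step multiplies an aging gene by
        # 2^(direction * effect), so consecutive-age contrasts see the same
        # planted magnitude as the tau contrast
        for gi, d in st["aging_dir"].items():
            mu[gi] *= 2.0 ** (d * spec.effect_log2fc * step)
    if genotype == "tau" and cl in spec.tau_affected_clusters:
        for gi, d in st["tau_dir"].items():
            mu[gi] *= 2.0 ** (d * spec.effect_log2fc)
    # immune-regulon expression scales with planted activity, and is further
    # activated by tau in the affected clusters
    rel_mult = 1.0 + st["activity"][cl]
    if genotype == "tau" and cl in spec.tau_affected_clusters:
        rel_mult *= spec.rel_activation
    mu[st["rel_members"]] *= rel_mult
    return mu


def _sample_counts(rng, mu_cells: np.ndarray, size: np.ndarray) -> np.ndarray:
    """NB(mean, size) counts via the gamma-Poisson mixture; mu_cells is G × n."""
    lam = rng.gamma(shape=size[:, None], scale=mu_cells / size[:, None])
    return rng.poisson(lam)


def simulate(spec: SimSpec):
    """Draw one synthetic study.

    Returns (Dataset, GroundTruth, regulon GeneSets).  Cells per cluster per
    library follow a multinomial whose weights in tau libraries are the base
    weights scaled by 2^(planted log2FC); gene counts are NB with planted
    aging/tau/regulon effects applied to the cluster-gene means.
    """
    st = _structure(spec)
    rng = np.random.default_rng(spec.seed)
    K = len(spec.clusters)
    G = spec.n_genes
    n_per_lib = spec.cells_per_cluster_per_library * K

    blocks = []
    meta_rows = []
    barcodes = []
    for genotype, age, rep in spec.libraries:
        lib = f"{genotype}_d{age}_r{rep}"
        w = st["base_weights"].copy()
        if genotype == "tau":
            w = w * 2.0 ** np.array([st["abundance"][c] for c in spec.clusters])
        w /= w.sum()
        n_k = rng.multinomial(n_per_lib, w)
        for k, cl in enumerate(spec.clusters):
            n = int(n_k[k])
            if n == 0:
                continue
            mu = _condition_means(spec, st, k, genotype, age)
            depth = np.exp(rng.normal(0.0, spec.libsize_sigma, size=n))
            counts = _sample_counts(rng, mu[:, None] * depth[None, :], st["size"])
            blocks.append(sp.csc_matrix(counts))
            start = len(barcodes)
            for j in range(n):
                barcodes.append(f"{lib}:c{start + j:05d}")
                meta_rows.append((lib, genotype, age, rep, cl))

    counts = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(
        meta_rows, columns=["library", "genotype", "age", "replicate", "cluster"],
        index=pd.Index(barcodes, name="barcode"),
    )
    ds = Dataset(
        counts=counts, genes=st["genes"], barcodes=pd.Index(barcodes),
        meta=meta, provenance={"source": "tauaging.simulate", "seed": spec.seed},
    )
    genes = st["genes"]
    truth = GroundTruth(
        abundance_log2fc=dict(st["abundance"]),
        regulon_activity=dict(st["activity"]),
        aging_genes={genes[i]: d for i, d in st["aging_dir"].items()},
        tau_genes={genes[i]: d for i, d in st["tau_dir"].items()},
        tau_shared={genes[i] for i in st["shared_idx"]},
        tau_unique={genes[i] for i in st["unique_idx"]},
        tau_affected_clusters=list(spec.tau_affected_clusters),
        anchor_clusters=list(spec.anchor_clusters),
        vulnerability_beta=spec.vulnerability_beta,
        seed=spec.seed,
    )
    return ds, truth, st["regulons"]


def simulate_reference_atlas(spec: SimSpec, perturb_sd: float = 0.1,
                             seed: int | None = None):
    """A second dataset from the same cluster-gene means, for annotation tests.

    Means are jittered lognormally (sd = ``perturb_sd``), sampling noise is
    independent, and cluster identities are preserved under permuted labels.
    Returns (Dataset, mapping source-cluster -> reference label).
    """
    st = _structure(spec)
    rng = np.random.default_rng((seed if seed is not None else spec.seed + 7919))
    K = len(spec.clusters)
    perm = rng.permutation(K)
    ref_label = {spec.clusters[k]: f"ref_{perm[k]:02d}" for k in range(K)}

    blocks, meta_rows, barcodes = [], [], []
    n = spec.cells_per_cluster_per_library
    for k, cl in enumerate(spec.clusters):
        mu = st["cluster_means"][k] * np.exp(
            rng.normal(0.0, perturb_sd, size=spec.n_genes)) if perturb_sd > 0 \
            else st["cluster_means"][k].copy()
        rel_mult = 1.0 + st["activity"][cl]
        mu = mu.copy()
        mu[st["rel_members"]] *= rel_mult
        depth = np.exp(rng.normal(0.0, spec.libsize_sigma, size=n))
        counts = _sample_counts(rng, mu[:, None] * depth[None, :], st["size"])
        blocks.append(sp.csc_matrix(counts))
        start = len(barcodes)
        for j in range(n):
            barcodes.append(f"ref:c{start + j:05d}")
            meta_rows.append(("reference", "control", 10, 0, ref_label[cl]))

    counts = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(
        meta_rows, columns=["library", "genotype", "age", "replicate", "cluster"],
        index=pd.Index(barcodes, name="barcode"),
    )
    ds = Dataset(counts=counts, genes=st["genes"], barcodes=pd.Index(barcodes),
                 meta=meta,
                 provenance={"source": "tauaging.simulate_reference_atlas",
                             "seed": spec.seed, "perturb_sd": perturb_sd})
    return ds, ref_label


# ---------------------------------------------------------------------------
# ortholog table generator
# ---------------------------------------------------------------------------

def simulate_ortholog_table(n_pairs: int, frac_multi: float = 0.3,
                            seed: int = 0):
    """A DIOPT-style ortholog candidate table with known correct picks.

    ``frac_multi`` of source (human-like) genes get 2-4 candidate target
    (fly-like) genes whose tie structure exercises every branch of the
    selection cascade (score, weighted score, best-bidirectional flag,
    lexicographic).  A small fraction of genes score entirely below the
    mapping threshold and are truly unmappable.  Returns (DataFrame, truth)
    where truth maps each source gene to its correct target or None.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, str | None] = {}
    n_multi = int(round(frac_multi * n_pairs))
    branches = ["score", "weighted", "flags", "lex"]
    for i in range(n_pairs):
        hg = f"HS{i:05d}"
        unmappable = rng.random() < 0.05
        if unmappable:
            sc = int(rng.integers(1, 5))
            rows.append((hg, f"FLY{i:05d}a", sc, sc + rng.random(), False, False))
            truth[hg] = None
            continue
        if i < n_multi:
            branch = branches[i % len(branches)]
            base = int(rng.integers(6, 14))
            w = float(np.round(rng.uniform(1, 5), 2))
            t = [f"FLY{i:05d}{s}" for s in "abc"]
            if branch == "score":
                rows += [(hg, t[0], base + 2, w, False, False),
                         (hg, t[1], base, w + 1, True, True)]
                truth[hg] = t[0]
            elif branch == "weighted":
                rows += [(hg, t[0], base, w + 1.5, False, False),
                         (hg, t[1], base, w, True, True)]
                truth[hg] = t[0]
            elif branch == "flags":
                rows += [(hg, t[0], base, w, False, True),
                         (hg, t[1], base, w, True, True),
                         (hg, t[2], base, w - 1, True, True)]
                truth[hg] = t[1]
            else:  # full tie -> lexicographically smallest target
                rows += [(hg, t[1], base, w, True, True),
                         (hg, t[0], base, w, True, True)]
                truth[hg] = t[0]
        else:
            sc = int(rng.integers(5, 16))
            fg = f"FLY{i:05d}a"
            rows.append((hg, fg, sc, sc + rng.random(), True, True))
            truth[hg] = fg
    table = pd.DataFrame(
        rows, columns=["human_gene", "fly_gene", "score", "weighted_score",
                       "best_forward", "best_reverse"],
    )
    return table, truth
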