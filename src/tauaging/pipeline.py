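"""Configuration and the config-driven pipeline runner.

A run is an ordered list of stages over a shared state: simulate -> qc ->
annotate / abundance / de / activity -> vulnerability / xspecies.  Every
tunable has a key in the default configuration; all randomness flows from
one root seed, fanned out per stage by stable stage-name hashing, and a
manifest (seeds, parameters, versions, row counts) is written next to the
stage outputs.  Two runs with the same config produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import abundance as ab
from . import activity as ac
from . import annotate as an
from . import crossspecies as xs
from . import de as de_mod
from . import qc as qc_mod
from importlib import import_module

sim = import_module("tauaging.simulate")  # the package re-exports simulate()
from . import vulnerability as vu
from .io import write_counts, write_gene_sets, write_json, write_meta

log = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "stage_seed", "run_pipeline",
           "PIPELINE_STAGES"]

PIPELINE_STAGES = ["simulate", "qc", "annotate", "abundance", "de",
                   "activity", "vulnerability", "xspecies"]


def default_config() -> dict:
    """The full default configuration; every stage tunable has a key."""
    return {
        "seed": 0,
        "stages": list(PIPELINE_STAGES),
        "simulate": {
            f.name: (f.default if f.default is not dataclasses.MISSING
                     else f.default_factory())
            for f in dataclasses.fields(sim.SimSpec)
        },
        "qc": {"min_genes": 200, "max_genes": 3000, "max_mito_frac": 0.20,
               "mito_prefix": "mt:"},
        "normalize": {"scale_constant": 10_000.0},
        "annotate": {"threshold": 0.7, "min_shared": 13, "n_features": 500,
                     "top_k": 20, "perturb_sd": 0.05,
                     "prioritize_optic_lobe": False},
        "de": {"min_cells": 10, "padj_threshold": 0.05, "lfc_threshold": 0.1,
               "pct_threshold": 0.10, "aging_pairs": [[1, 10], [10, 20]]},
        "abundance": {"design": "age+genotype", "shrink": False,
                      "pseudocount": None},
        "activity": {"method": "mean", "top_fraction": 0.05,
                     "auc_normalization": "B"},
        "vulnerability": {"k": 3, "repeats": 10, "n_alpha": 6, "n_lambda": 15,
                          "direction": "decline", "allow_small": True},
        "xspecies": {"min_score": 5, "n_ortholog_pairs": 400,
                     "frac_multi": 0.3},
    }


def load_config(path=None) -> dict:
    """Load a YAML config, overlaying it on the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def stage_seed(root_seed: int, stage: str) -> int:
    """Fan the root seed out per stage by stable name hashing (below 2^31)."""
    return (int(root_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages, writing TSV/JSON results and a manifest.

    Unknown stage names raise before any stage runs.  Returns the final
    state dict (datasets and result tables) for programmatic use.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", []))
    unknown = [s for s in stages if s not in PIPELINE_STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stages: {unknown}")

    state: dict = {}
    manifest = {"version": __version__, "seed": config.get("seed", 0),
                "stages": stages, "config": _jsonable(config), "rows": {}}
    for stage in stages:
        log.info("stage %s: start", stage)
        _STAGE_FUNCS[stage](config, state, out, manifest)
        log.info("stage %s: done", stage)
    write_json(manifest, out / "manifest.json")
    return state


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


# --- stages ---------------------------------------------------------------

def _stage_simulate(config, state, out, manifest):
    seed = stage_seed(config["seed"], "simulate")
    spec_kwargs = dict(config["simulate"])
    spec_kwargs["seed"] = seed
    spec = sim.SimSpec(**spec_kwargs)
    ds, truth, regulons = sim.simulate(spec)
    state.update(ds=ds, truth=truth, regulons=regulons, spec=spec)
    write_counts(ds, out / "counts")
    write_meta(ds.meta, out / "meta.tsv")
    write_gene_sets(regulons, out / "regulons.gmt")
    write_json({
        "abundance_log2fc": truth.abundance_log2fc,
        "regulon_activity": truth.regulon_activity,
        "aging_genes": truth.aging_genes,
        "tau_genes": truth.tau_genes,
        "tau_shared": sorted(truth.tau_shared),
        "tau_unique": sorted(truth.tau_unique),
        "seed": truth.seed,
    }, out / "truth.json")
    manifest["rows"]["simulate"] = ds.n_cells
    manifest.setdefault("stage_seeds", {})["simulate"] = seed


def _stage_qc(config, state, out, manifest):
    thr = qc_mod.QCThresholds(**{k: v for k, v in config["qc"].items()
                                 if k in ("min_genes", "max_genes",
                                          "max_mito_frac", "mito_prefix")})
    ds, report = qc_mod.filter_cells(state["ds"], thr, return_report=True)
    state["ds"] = ds
    state["nm"] = qc_mod.lognormalize(ds, config["normalize"]["scale_constant"])
    _write_tsv(pd.DataFrame([report]), out / "qc_report.tsv", index=False)
    write_counts(ds, out / "counts_filtered")
    manifest["rows"]["qc"] = ds.n_cells


def _require_nm(config, state):
    if "nm" not in state:
        state["nm"] = qc_mod.lognormalize(
            state["ds"], config["normalize"]["scale_constant"])
    return state["nm"]


def _stage_annotate(config, state, out, manifest):
    acfg = config["annotate"]
    seed = stage_seed(config["seed"], "annotate")
    ref_ds, perm = sim.simulate_reference_atlas(
        state["spec"], perturb_sd=acfg["perturb_sd"], seed=seed)
    ref_nm = qc_mod.lognormalize(ref_ds, config["normalize"]["scale_constant"])
    atlas = an.build_reference_atlas(ref_ds, ref_nm, ref_ds.meta["cluster"],
                                     n_features=acfg["n_features"],
                                     top_k=acfg["top_k"])
    nm = _require_nm(config, state)
    result = an.annotate_clusters(
        state["ds"], nm, state["ds"].meta["cluster"], atlas,
        threshold=acfg["threshold"], min_shared=acfg["min_shared"],
        top_k=acfg["top_k"],
        prioritize_optic_lobe=acfg["prioritize_optic_lobe"])
    result = result.sort_index()
    state["annotation"] = result
    state["annotation_truth_map"] = perm
    _write_tsv(result, out / "annotation.tsv")
    manifest["rows"]["annotate"] = len(result)
    manifest.setdefault("stage_seeds", {})["annotate"] = seed


def _stage_abundance(config, state, out, manifest):
    tbl = ab.count_cells(state["ds"].meta)
    records = ab.fit_abundance(tbl, design=config["abundance"]["design"],
                               size_factor_pseudocount=config["abundance"]["pseudocount"])
    if config["abundance"]["shrink"]:
        records = ab.shrink_lfc(records)
    anchors = [c for c in state["spec"].anchor_clusters if c in records.index] \
        if "spec" in state else list(records.index[:1])
    ranges = ab.anchor_adjust(records, anchors)
    state["abundance"] = records
    state["anchored"] = ranges
    _write_tsv(tbl.counts, out / "cluster_counts.tsv")
    _write_tsv(records, out / "abundance.tsv")
    _write_tsv(ranges, out / "abundance_anchored.tsv")
    manifest["rows"]["abundance"] = len(records)


def _stage_de(config, state, out, manifest):
    nm = _require_nm(config, state)
    meta = state["ds"].meta
    dcfg = config["de"]
    kwargs = dict(min_cells=dcfg["min_cells"],
                  padj_threshold=dcfg["padj_threshold"],
                  lfc_threshold=dcfg["lfc_threshold"],
                  pct_threshold=dcfg["pct_threshold"])
    tables = []
    tau = de_mod.de_test(nm, meta, de_mod.tau_design(), **kwargs)
    tau.insert(0, "contrast", "tau-vs-control")
    tables.append(tau)
    for lo, hi in dcfg["aging_pairs"]:
        t = de_mod.de_test(nm, meta, de_mod.aging_design((lo, hi)), **kwargs)
        t.insert(0, "contrast", f"aging-{lo}v{hi}")
        tables.append(t)
    full = pd.concat(tables, ignore_index=True)
    state["de"] = full
    tau_sets = de_mod.significant_gene_sets(tau)
    aging_sets: dict = {}
    for t in tables[1:]:
        for cl, genes in de_mod.significant_gene_sets(t).items():
            aging_sets.setdefault(cl, set()).update(genes)
    overlap, per_cluster = de_mod.overlap_statistic(tau_sets, aging_sets)
    state["overlap"] = overlap
    _write_tsv(full, out / "de.tsv", index=False)
    write_json({"global_overlap_fraction": overlap,
                "per_cluster": {str(k): v for k, v in per_cluster.items()}},
               out / "overlap.json")
    manifest["rows"]["de"] = len(full)


def _stage_activity(config, state, out, manifest):
    nm = _require_nm(config, state)
    meta = state["ds"].meta
    acfg = config["activity"]
    if acfg["method"] == "auc":
        act = ac.auc_activity(nm, state["regulons"],
                              top_fraction=acfg["top_fraction"],
                              normalization=acfg["auc_normalization"])
    else:
        act = ac.mean_activity(nm, state["regulons"])
    state["activity"] = act
    lfc = ac.cluster_activity_lfc(act, meta)
    diff = ac.differential_activity(act, meta)
    state["activity_lfc"] = lfc
    _write_tsv(lfc, out / "activity_log2fc.tsv")
    _write_tsv(diff, out / "activity_lrt.tsv", index=False)
    manifest["rows"]["activity"] = act.values.shape[0]


def _stage_vulnerability(config, state, out, manifest):
    vcfg = config["vulnerability"]
    seed = stage_seed(config["seed"], "vulnerability")
    design = vu.build_design(state["abundance"], state["activity"],
                             state["ds"].meta, direction=vcfg["direction"],
                             allow_small=vcfg["allow_small"])
    if design.X.shape[1] == 0 or len(design.y) < 2:
        log.warning("vulnerability design degenerate (%d rows, %d predictors);"
                    " stage skipped", len(design.y), design.X.shape[1])
        state["ranklist"] = pd.Series(dtype=float, name="coefficient")
        state["decline_correlation"] = {}
        _write_tsv(state["ranklist"].rename("Elastic net coefficient")
                   .rename_axis("Term").to_frame(),
                   out / "vulnerability_ranklist.tsv")
        write_json({"skipped": "degenerate design"},
                   out / "vulnerability_model.json")
        manifest["rows"]["vulnerability"] = 0
        return
    model = vu.tune(design,
                    alpha_grid=vu.default_alpha_grid(vcfg["n_alpha"]),
                    lambda_grid=vu.default_lambda_grid(design, vcfg["n_lambda"]),
                    k=min(vcfg["k"], len(design.y)),
                    repeats=vcfg["repeats"], seed=seed)
    ranklist = vu.rank_predictors(model)
    state["vulnerability_model"] = model
    state["ranklist"] = ranklist
    rel_col = "Rel-like" if "Rel-like" in state["activity"].values.columns else None
    corr = {}
    if rel_col:
        pooled = state["activity"].values.groupby(
            state["ds"].meta.loc[state["activity"].cells, "cluster"]).mean()
        try:
            r, p = vu.activity_decline_correlation(pooled[rel_col],
                                                   state["abundance"])
            corr = {"set": rel_col, "pearson_r": r, "p": p}
        except ValueError as exc:
            corr = {"set": rel_col, "error": str(exc)}
    state["decline_correlation"] = corr
    _write_tsv(ranklist.rename("Elastic net coefficient").rename_axis("Term")
               .to_frame(), out / "vulnerability_ranklist.tsv")
    write_json({"alpha": model.alpha, "lambda": model.lam,
                "cv_rmse": model.cv_rmse, "intercept": model.intercept,
                "decline_correlation": corr}, out / "vulnerability_model.json")
    manifest["rows"]["vulnerability"] = len(ranklist)
    manifest.setdefault("stage_seeds", {})["vulnerability"] = seed


def _stage_xspecies(config, state, out, manifest):
    xcfg = config["xspecies"]
    seed = stage_seed(config["seed"], "xspecies")
    nm = _require_nm(config, state)
    z = qc_mod.scale_genes(nm)
    prof_a = xs.cluster_mean_profiles(z, state["ds"].meta["cluster"])
    ref_ds, perm = sim.simulate_reference_atlas(state["spec"], perturb_sd=0.05,
                                                seed=seed)
    ref_z = qc_mod.scale_genes(
        qc_mod.lognormalize(ref_ds, config["normalize"]["scale_constant"]))
    prof_b = xs.cluster_mean_profiles(ref_z, ref_ds.meta["cluster"])
    mat, row_order, col_order = xs.correspondence(prof_a, prof_b)
    state["correspondence"] = mat
    state["xspecies_truth_map"] = perm
    table, truth = sim.simulate_ortholog_table(
        xcfg["n_ortholog_pairs"], frac_multi=xcfg["frac_multi"], seed=seed)
    resolved = xs.select_orthologs(table, min_score=xcfg["min_score"])
    state["orthologs"] = resolved
    _write_tsv(mat, out / "correspondence.tsv")
    _write_tsv(mat.loc[row_order, col_order], out / "correspondence_ordered.tsv")
    _write_tsv(resolved, out / "orthologs_resolved.tsv", index=False)
    manifest["rows"]["xspecies"] = mat.shape[0]
    manifest.setdefault("stage_seeds", {})["xspecies"] = seed


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "annotate": _stage_annotate,
    "abundance": _stage_abundance,
    "de": _stage_de,
    "activity": _stage_activity,
    "vulnerability": _stage_vulnerability,
    "xspecies": _stage_xspecies,
}
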