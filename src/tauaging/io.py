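"""Readers and writers for the on-disk formats used throughout the pipeline.

Count matrices travel as a 10x-style triplet (MatrixMarket ``.mtx`` plus
``features.tsv`` / ``barcodes.tsv``), gene sets as GMT, tables as TSV and
manifests as JSON.  The in-memory contract is fixed: genes are rows, cells
are columns, counts are non-negative integers.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "Dataset",
    "GeneSet",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_gene_sets",
    "write_gene_sets",
    "read_meta",
    "write_meta",
    "nfkb_gene_set",
]


class FormatError(ValueError):
    """An on-disk file violates the format contract."""


@dataclass
class GeneSet:
    """A named gene set (coexpression module, regulon or curated pathway).

    Members are de-duplicated preserving first-occurrence order.
    """

    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        deduped = []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                deduped.append(g)
        self.genes = deduped

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Dataset:
    """A gene × cell count matrix with per-cell metadata.

    Attributes
    ----------
    counts : scipy.sparse.csr_matrix
        Non-negative integer counts, genes as rows, cells as columns.
    genes : pd.Index
        Unique gene identifiers (row labels).
    barcodes : pd.Index
        Unique cell barcodes (column labels).
    meta : pd.DataFrame
        One row per cell, indexed by barcode; typical columns are
        ``library``, ``genotype``, ``age``, ``cluster``.
    provenance : dict
        Free-form source / seed record carried through the pipeline.
    """

    counts: sp.spmatrix
    genes: pd.Index
    barcodes: pd.Index
    meta: pd.DataFrame = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes)
        self.barcodes = pd.Index(self.barcodes)
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.barcodes)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes:
            raise FormatError(
                f"{len(self.genes)} gene ids for a matrix with {n_genes} rows"
            )
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for a matrix with {n_cells} columns"
            )
        if not self.genes.is_unique:
            raise FormatError("gene identifiers are not unique")
        if not self.barcodes.is_unique:
            raise FormatError("cell barcodes are not unique")
        if len(self.meta) != n_cells:
            raise FormatError("meta rows do not match number of cells")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise FormatError("counts contain non-integer entries")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask_or_idx) -> "Dataset":
        """Return a new Dataset restricted to the given cells (bool mask or indices)."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Dataset(
            counts=self.counts[:, idx],
            genes=self.genes,
            barcodes=self.barcodes[idx],
            meta=self.meta.iloc[idx],
            provenance=dict(self.provenance),
        )


# -- 10x-style triplet ----------------------------------------------------

def read_counts(matrix_path, features_path, barcodes_path) -> Dataset:
    """Read a MatrixMarket + features/barcodes triplet into a Dataset.

    The matrix header must agree with the feature/barcode counts and all
    entries must be non-negative integers.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy's message suffices
        raise FormatError(f"cannot parse MatrixMarket file: {exc}") from exc
    genes = _read_single_column_tsv(features_path)
    barcodes = _read_single_column_tsv(barcodes_path)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape} but triplet announces "
            f"{len(genes)} features × {len(barcodes)} barcodes"
        )
    return Dataset(counts=mat, genes=pd.Index(genes), barcodes=pd.Index(barcodes))


def _read_single_column_tsv(path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def write_counts(ds: Dataset, out_dir) -> dict[str, Path]:
    """Write a Dataset as matrix.mtx / features.tsv / barcodes.tsv under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    coo = sp.coo_matrix(ds.counts)
    scipy.io.mmwrite(
        str(paths["matrix"]),
        sp.coo_matrix((coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape),
        field="integer",
    )
    paths["features"].write_text("".join(f"{g}\n" for g in ds.genes))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in ds.barcodes))
    return paths


# -- per-cell metadata -----------------------------------------------------

def read_meta(path) -> pd.DataFrame:
    """Read a per-cell metadata TSV indexed by barcode."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if not meta.index.is_unique:
        raise FormatError("metadata barcodes are not unique")
    return meta


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="barcode")


# -- GMT gene sets ---------------------------------------------------------

def read_gene_sets(path) -> list[GeneSet]:
    """Read a GMT file (name, description, members...) into GeneSets.

    Set names must be unique; a line with an empty member list is skipped
    with a warning.
    """
    import warnings

    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                if len(parts) == 2:
                    warnings.warn(
                        f"{path}:{lineno}: gene set '{parts[0]}' has no members; skipped"
                    )
                    continue
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need >=3 tab-separated fields"
                )
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                warnings.warn(
                    f"{path}:{lineno}: gene set '{name}' has no members; skipped"
                )
                continue
            if name in names:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name '{name}'")
            names.add(name)
            sets.append(GeneSet(name=name, genes=members, description=desc))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "."] + list(s.genes)) + "\n")


def nfkb_gene_set() -> GeneSet:
    """The packaged 62-gene curated fly NFκB/Imd/Toll signaling set."""
    ref = importlib.resources.files("tauaging.data") / "nfkb_signaling.gmt"
    with importlib.resources.as_file(ref) as p:
        return read_gene_sets(p)[0]


# -- JSON manifests --------------------------------------------------------

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
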