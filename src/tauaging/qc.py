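"""Cell-level quality control and normalization.

Cells are retained when 200 <= detected genes <= 3000 and the mitochondrial
read fraction is at most 20% (boundaries inclusive: the removal rule is a
strict inequality on either side).  Expression is normalized per cell —
counts divided by the cell's UMI total, scaled by 10,000 and ln(1+x)
transformed — and optionally z-scored per gene for cross-dataset
comparisons.  The cellular detection rate (CDR, fraction of genes with a
nonzero count in a cell) is the standard technical covariate for the hurdle
differential-expression model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import Dataset

log = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "NormalizedMatrix",
    "filter_cells",
    "lognormalize",
    "compute_cdr",
    "expected_doublet_rate",
    "scale_genes",
]


@dataclass
class QCThresholds:
    """Retention bounds for cell-level QC.

    A cell is removed if detected genes < ``min_genes``, > ``max_genes``,
    or its mitochondrial count fraction exceeds ``max_mito_frac``.
    Mitochondrial genes are recognised by identifier prefix (fly
    convention ``mt:``) unless an explicit list is given.
    """

    min_genes: int = 200
    max_genes: int = 3000
    max_mito_frac: float = 0.20
    mito_prefix: str = "mt:"
    mito_genes: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must lie in [0, 1]")


@dataclass
class NormalizedMatrix:
    """A dense real gene × cell expression matrix with a transform tag."""

    values: np.ndarray  # genes × cells
    genes: pd.Index
    cells: pd.Index
    transform: str = "lognorm"  # "lognorm" | "zscore"
    scale_constant: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape does not match gene/cell labels")
        if self.transform not in ("lognorm", "zscore"):
            raise ValueError(f"unknown transform tag {self.transform!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def _mito_mask(genes: pd.Index, thr: QCThresholds) -> np.ndarray:
    if thr.mito_genes is not None:
        return genes.isin(thr.mito_genes)
    return np.array([g.startswith(thr.mito_prefix) for g in genes])


def filter_cells(
    ds: Dataset, thr: QCThresholds | None = None, return_report: bool = False
):
    """Remove low-quality cells; boundary values are retained.

    Returns the filtered Dataset (and, optionally, a per-criterion removal
    report).  Raises ``ValueError`` naming the binding criterion when no
    cell survives.
    """
    thr = thr or QCThresholds()
    counts = sp.csc_matrix(ds.counts)
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito = _mito_mask(ds.genes, thr)
    mito_counts = np.asarray(counts[mito].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1.0), 0.0)

    low = detected < thr.min_genes
    high = detected > thr.max_genes
    mito_bad = mito_frac > thr.max_mito_frac
    keep = ~(low | high | mito_bad)

    report = {
        "n_input": ds.n_cells,
        "removed_low_genes": int(low.sum()),
        "removed_high_genes": int(high.sum()),
        "removed_mito": int(mito_bad.sum()),
        "n_retained": int(keep.sum()),
    }
    log.info("QC filter: %s", report)
    if report["n_retained"] == 0:
        binding = max(
            ("removed_low_genes", "removed_high_genes", "removed_mito"),
            key=lambda k: report[k],
        )
        raise ValueError(f"no cells survive QC; binding criterion: {binding}")
    out = ds.subset_cells(keep)
    if return_report:
        return out, report
    return out


def lognormalize(ds: Dataset, scale_constant: float = 10_000.0) -> NormalizedMatrix:
    """Per-cell depth normalization: ln(1 + scale * count / cell_total)."""
    counts = sp.csc_matrix(ds.counts, dtype=float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        raise ValueError(
            "cells with zero total UMIs present; run filter_cells first"
        )
    norm = counts.multiply(scale_constant / totals)  # broadcasts over columns
    values = np.log1p(np.asarray(norm.todense()))
    return NormalizedMatrix(
        values=values,
        genes=ds.genes,
        cells=ds.barcodes,
        transform="lognorm",
        scale_constant=scale_constant,
    )


def compute_cdr(ds: Dataset) -> pd.Series:
    """Cellular detection rate: fraction of the gene universe detected per cell."""
    detected = np.asarray((ds.counts > 0).sum(axis=0)).ravel()
    return pd.Series(detected / ds.n_genes, index=ds.barcodes, name="cdr")


def expected_doublet_rate(n_recovered_cells: int) -> float:
    """Expected multiplet proportion for a 10x run with *n* recovered cells.

    Linear in the number of recovered cells (Y = 5.272e-4 + 7.589e-6 * n,
    from the droplet loading tables), clamped to [0, 1].
    """
    if n_recovered_cells < 0:
        raise ValueError("cell count must be non-negative")
    rate = 5.272e-4 + 7.589e-6 * n_recovered_cells
    return float(min(max(rate, 0.0), 1.0))


def scale_genes(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Z-score each gene across cells (population sd).

    Zero-variance genes become all-zero rows, with a warning.
    """
    if nm.transform != "lognorm":
        raise ValueError("scale_genes expects a lognorm matrix")
    mean = nm.values.mean(axis=1, keepdims=True)
    sd = nm.values.std(axis=1, keepdims=True)  # population sd (ddof=0)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance genes set to all-zero rows")
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (nm.values - mean) / safe_sd
    z[flat, :] = 0.0
    return NormalizedMatrix(
        values=z,
        genes=nm.genes,
        cells=nm.cells,
        transform="zscore",
        scale_constant=nm.scale_constant,
    )
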