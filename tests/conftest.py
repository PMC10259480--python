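import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import tauaging as ta


@pytest.fixture(scope="session")
def small_study():
    """A small full-design synthetic study shared across read-only tests."""
    spec = ta.SimSpec(cells_per_cluster_per_library=60, n_regulons=20, seed=7)
    ds, truth, regulons = ta.simulate(spec)
    return {"spec": spec, "ds": ds, "truth": truth, "regulons": regulons}


@pytest.fixture(scope="session")
def small_lognorm(small_study):
    return ta.lognormalize(small_study["ds"])


@pytest.fixture()
def tiny_dataset():
    """Hand-built 4-gene x 5-cell dataset for exact arithmetic checks."""
    counts = sp.csr_matrix(np.array([
        [5, 0, 1, 0, 2],
        [0, 0, 3, 1, 0],
        [2, 4, 0, 0, 1],
        [0, 1, 0, 0, 0],
    ]))
    genes = pd.Index(["g1", "g2", "mt:g3", "g4"])
    barcodes = pd.Index([f"c{i}" for i in range(5)])
    meta = pd.DataFrame({
        "library": ["L1", "L1", "L1", "L2", "L2"],
        "genotype": ["control", "control", "tau", "tau", "control"],
        "age": [1, 10, 20, 10, 1],
        "cluster": ["A", "A", "B", "B", "A"],
    }, index=barcodes)
    return ta.Dataset(counts=counts, genes=genes, barcodes=barcodes, meta=meta)
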