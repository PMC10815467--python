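import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import igrn
from igrn.io import CountMatrix, NormalizedMatrix


@pytest.fixture(scope="session")
def bundle():
    """The pinned small synthetic bundle (shared, read-only)."""
    return igrn.fixture_small()


@pytest.fixture(scope="session")
def default_bundle():
    """One default-conditions bundle (shared, read-only)."""
    return igrn.generate(igrn.SynthConfig(), seed=1)


def make_counts(array, genes=None, barcodes=None) -> CountMatrix:
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    barcodes = barcodes or [f"c{j}" for j in range(array.shape[1])]
    return CountMatrix(genes, barcodes, sp.csr_matrix(array))


def make_normalized(array, genes=None, barcodes=None) -> NormalizedMatrix:
    array = np.asarray(array, dtype=float)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    barcodes = barcodes or [f"c{j}" for j in range(array.shape[1])]
    return NormalizedMatrix(genes, barcodes, sp.csr_matrix(array))


def make_cells(barcodes, subclusters, cell_types=None, groups=None) -> pd.DataFrame:
    return pd.DataFrame({
        "barcode": barcodes,
        "sample": "S1",
        "group": groups if groups is not None else "tumor",
        "cell_type": cell_types if cell_types is not None else subclusters,
        "subcluster": subclusters,
    })
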