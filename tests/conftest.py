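import numpy as np
import pandas as pd
import pytest

from ervregnet.expression import ExpressionMatrix, GERMLINE_CELL_TYPES


def matrix_from_blocks(per_type_counts, n_cells=2):
    """Build an ExpressionMatrix from per-cell-type count columns.

    ``per_type_counts`` maps feature -> dict cell_type -> count; each cell
    type gets ``n_cells`` identical cells.
    """
    features = list(per_type_counts)
    cols, meta_rows, data = [], [], []
    for ct in GERMLINE_CELL_TYPES:
        for i in range(n_cells):
            cols.append(f"{ct}_{i}")
            meta_rows.append(ct)
            data.append([per_type_counts[f][ct] for f in features])
    counts = pd.DataFrame(np.array(data).T, index=features, columns=cols)
    meta = pd.DataFrame({"cell_type": meta_rows}, index=pd.Index(cols, name="cell_id"))
    return ExpressionMatrix(counts, meta)


@pytest.fixture
def random_matrix():
    """Random germline-series count matrix, 50 features x 60 cells."""
    rng = np.random.default_rng(7)
    cols, types = [], []
    for ct in GERMLINE_CELL_TYPES:
        for i in range(10):
            cols.append(f"{ct}_{i}")
            types.append(ct)
    counts = pd.DataFrame(
        rng.poisson(5, size=(50, 60)) + (rng.random((50, 60)) < 0.1),
        index=[f"f{i}" for i in range(50)],
        columns=cols,
    )
    meta = pd.DataFrame({"cell_type": types}, index=pd.Index(cols, name="cell_id"))
    return ExpressionMatrix(counts, meta)


@pytest.fixture
def toy_genome():
    return {"chr1": 1_000_000, "chr2": 500_000}
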