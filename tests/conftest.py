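import numpy as np
import pandas as pd
import pytest

from winemap import simulate


@pytest.fixture(scope="session")
def sparse_map():
    """Full 16-chromosome map at reduced marker density (fast pipeline tests)."""
    return simulate.simulate_marker_map(density_per_10kbp=0.3, seed=11)


@pytest.fixture(scope="session")
def cross44(sparse_map):
    """A default-size cross (44 viable segregants) with the translocation."""
    return simulate.simulate_cross(sparse_map, n_segregants=44, seed=11)


@pytest.fixture()
def two_marker_map():
    """Two markers 20 cM apart on one chromosome."""
    table = pd.DataFrame(
        {
            "marker_id": ["a", "b"],
            "chrom": [1, 1],
            "pos_kbp": [3.0, 63.0],
            "pos_cM": [1.0, 21.0],
        }
    )
    return simulate.MarkerMap(table)


def make_expression(values, sample_ids=None, chrom=1):
    """Wrap a raw array as an ExpressionMatrix with dummy annotation."""
    values = np.asarray(values, dtype=float)
    genes = [f"g{i + 1:04d}" for i in range(values.shape[0])]
    annot = pd.DataFrame(
        {"chrom": chrom, "pos_kbp": np.linspace(10, 200, values.shape[0])}, index=genes
    )
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(values.shape[1])]
    return simulate.ExpressionMatrix(values, genes, annot, list(sample_ids))
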