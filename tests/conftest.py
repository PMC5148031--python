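import numpy as np
import pandas as pd
import pytest

from rifseq.io import CountMatrix, SampleDesign
from rifseq.normalization import NormalizedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    """4 genes x 6 samples, hand-sized integers."""
    data = {
        "a1": [10, 0, 55, 3],
        "a2": [12, 1, 60, 2],
        "a3": [9, 0, 48, 5],
        "b1": [11, 2, 80, 0],
        "b2": [8, 0, 75, 1],
        "b3": [13, 1, 90, 0],
    }
    return CountMatrix(pd.DataFrame(data, index=["g1", "g2", "g3", "g4"]))


@pytest.fixture
def small_meta(small_counts):
    return pd.DataFrame(
        {"length_bp": [1000, 500, 2000, 800]},
        index=pd.Index(small_counts.gene_ids, name="gene_id"),
    )


@pytest.fixture
def small_design():
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
                "condition": ["A", "A", "A", "B", "B", "B"],
            }
        ),
        ("A", "B"),
    )


def make_norm(fpkm: pd.DataFrame) -> NormalizedMatrix:
    """NormalizedMatrix straight from an FPKM table (unit factors/libs)."""
    return NormalizedMatrix(
        fpkm=fpkm,
        log_expr=np.log2(fpkm + 1.0),
        lib_size=pd.Series(1_000_000, index=fpkm.columns),
        tmm_factor=pd.Series(1.0, index=fpkm.columns),
    )


@pytest.fixture
def make_norm_factory():
    return make_norm
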