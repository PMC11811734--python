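import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from scxaa.datamodel import CellMatrix, GeneAnnotation

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_annotation():
    """Four autosomal + three X genes, one of them an XCI escapee."""
    genes = ["a1", "a2", "a3", "a4", "x1", "x2", "x3"]
    return GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome_class": ["autosome"] * 4 + ["X"] * 3,
                "is_xe": [False] * 4 + [True, False, False],
                "gene_length_bp": [1000, 2000, 500, 1000, 1000, 1500, 800],
            },
            index=pd.Index(genes, name="gene_id"),
        )
    )


@pytest.fixture
def small_matrix():
    genes = ["a1", "a2", "a3", "a4", "x1", "x2", "x3"]
    cells = ["c1", "c2", "c3"]
    vals = pd.DataFrame(
        [
            [1.0, 0.0, 2.0],
            [2.0, 3.0, 0.0],
            [0.0, 0.0, 1.0],
            [4.0, 1.0, 3.0],
            [8.0, 2.0, 0.0],
            [0.5, 0.0, 1.0],
            [1.0, 4.0, 2.0],
        ],
        index=genes,
        columns=cells,
    )
    return CellMatrix(values=vals, unit="FPKM", tissue="testis")
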