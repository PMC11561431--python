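import numpy as np
import pandas as pd
import pytest

from behavdet import synthetic
from behavdet.clustering import DissimilarityMatrix
from behavdet.io import Codebook, ResponseMatrix


@pytest.fixture(scope="session")
def two_block_D() -> DissimilarityMatrix:
    """Six items in two tight blocks: D=0.1 within, 0.9 across (ultrametric)."""
    items = ("a1", "a2", "a3", "b1", "b2", "b3")
    D = np.full((6, 6), 0.9)
    D[:3, :3] = 0.1
    D[3:, 3:] = 0.1
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(items=items, values=D)


@pytest.fixture(scope="session")
def strong_dataset() -> synthetic.SyntheticDataset:
    """Three signal blocks with strong intention effects plus noise items."""
    return synthetic.generate(synthetic.strong_signal_design(seed=3))


@pytest.fixture(scope="session")
def small_codebook() -> Codebook:
    return Codebook.from_records(
        [
            {"id": "q1", "role": "predictor", "scale": "likert5"},
            {"id": "q2", "role": "predictor", "scale": "likert5",
             "reverse_coded": True},
            {"id": "age", "role": "demographic", "scale": "categorical"},
            {"id": "intention", "role": "outcome", "scale": "likert5"},
        ]
    )


@pytest.fixture()
def small_matrix(small_codebook) -> ResponseMatrix:
    data = pd.DataFrame(
        {
            "q1": [1, 2, 3, 4, 5, 3],
            "q2": [5, 4, 3, 2, 1, 3],  # already harmonized in-memory
            "age": ["young", "old", "old", "young", "old", "young"],
            "intention": [1, 2, 2, 3, 5, 1],
        },
        index=pd.RangeIndex(1, 7, name="respondent_id"),
    )
    return ResponseMatrix(data=data, codebook=small_codebook)
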