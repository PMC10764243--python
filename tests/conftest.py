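import numpy as np
import pytest

from mbcdeg.io_core import CountMatrix, GroupDesign
from mbcdeg.normalization import NormalizationFactors, cpm_factors
from mbcdeg.simulator import replica_sample_dataset


@pytest.fixture(scope="session")
def replica():
    """The 2,000-gene x 11-sample worked dataset (seed 1) with its design and truth."""
    return replica_sample_dataset(seed=1)


@pytest.fixture(scope="session")
def replica_fit(replica):
    """Full pipeline result on the replica dataset, K=3, seed 1."""
    from mbcdeg.deg_calling import run_pipeline

    matrix, design, _ = replica
    norm = cpm_factors(matrix)
    return run_pipeline(matrix, design, norm.log_factor, K=3, seed=1)


@pytest.fixture
def small_counts():
    """A tiny 4-gene, 4-sample two-group matrix with unit factors."""
    counts = np.array(
        [
            [10, 14, 3, 5],
            [100, 120, 110, 90],
            [0, 1, 2, 0],
            [40, 36, 160, 144],
        ]
    )
    matrix = CountMatrix(
        gene_ids=[f"g{i}" for i in range(1, 5)],
        sample_ids=["X1", "X2", "Y1", "Y2"],
        counts=counts,
    )
    design = GroupDesign.from_labels(["X", "X", "Y", "Y"])
    norm = NormalizationFactors.from_factor("unit", np.ones(4))
    return matrix, design, norm
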