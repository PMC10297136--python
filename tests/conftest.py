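import numpy as np
import pytest

from mbfpath import FusionCovariates, MutationMatrix


def make_matrix(entries, patients=None, genes=None) -> MutationMatrix:
    arr = np.asarray(entries, dtype=np.uint8)
    m, n = arr.shape
    patients = patients or [f"P{i}" for i in range(m)]
    genes = genes or [f"G{j}" for j in range(n)]
    return MutationMatrix(arr, patients, genes)


@pytest.fixture
def overlap_matrix() -> MutationMatrix:
    """Two genes with supports {0,1,2} and {2,3} among 5 patients."""
    return make_matrix(
        [
            [1, 0],
            [1, 0],
            [1, 1],
            [0, 1],
            [0, 0],
        ]
    )


@pytest.fixture
def neutral2() -> FusionCovariates:
    return FusionCovariates.neutral(2)
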