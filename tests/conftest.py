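import numpy as np
import pytest

from recscreen import RunConfig, SignatureTensor


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig(seed=0)


def build_tensor(z: np.ndarray, compounds=None, genes=None,
                 cell_lines=None, timepoints=None) -> SignatureTensor:
    """Tensor from a raw (compound, gene, cell_line, timepoint) array with
    auto-generated labels."""
    z = np.asarray(z, dtype=float)
    C, G, L, T = z.shape
    return SignatureTensor.from_array(
        z,
        compounds or [f"c{i}" for i in range(C)],
        genes or [f"g{i}" for i in range(G)],
        cell_lines or [f"l{i}" for i in range(L)],
        timepoints or ([f"t{i}" for i in range(T)] if T != 2 else ["6h", "24h"]),
    )


@pytest.fixture
def tensor_builder():
    return build_tensor
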