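import numpy as np
import pytest

from dabench.counts_io import CountMatrix, GroupDesign
from dabench.synthetic_source import generate_reference, preset


@pytest.fixture
def small_matrix():
    """4 genes x 6 samples with equal column totals (=20)."""
    counts = np.array(
        [
            [1, 2, 3, 4, 5, 6],
            [9, 8, 7, 6, 5, 4],
            [4, 6, 2, 8, 1, 9],
            [6, 4, 8, 2, 9, 1],
        ]
    )
    return CountMatrix(("gA", "gB", "gC", "gD"), tuple(f"s{i}" for i in range(6)), counts)


@pytest.fixture
def design6():
    return GroupDesign(tuple(f"s{i}" for i in range(6)), ("A", "A", "A", "B", "B", "B"))


@pytest.fixture(scope="session")
def pyro_reference():
    """Session-shared pyrosequencing-style synthetic reference."""
    return generate_reference(preset("pyro_like", seed=20607))
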