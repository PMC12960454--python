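import numpy as np
import pytest

from coss.lattice import lattice_from_axial


@pytest.fixture
def hex_lattice_10x10():
    """Complete 10x10 hexagonal patch, unit spacing."""
    return lattice_from_axial(
        [(q, r) for q in range(10) for r in range(10)], "hexagonal", 1.0
    )


@pytest.fixture
def square_lattice_5x5():
    return lattice_from_axial(
        [(x, y) for x in range(5) for y in range(5)], "square", 1.0
    )


@pytest.fixture
def path_lattice():
    """Three collinear square-lattice wells a-b-c."""
    return lattice_from_axial([(0, 0), (1, 0), (2, 0)], "square", 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
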