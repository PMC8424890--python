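import numpy as np
import pytest

from siftmat._tables import default_mask_spec, mask_array
from siftmat.constants import COL_INDEX, N_COLS, N_ROWS, ROW_INDEX
from siftmat.engine import GeometryParams, build_matrix
from siftmat.fixtures import make_showcase_complex
from siftmat.matrix import InteractionMatrix, ResidueBlock


@pytest.fixture(scope="session")
def default_params():
    return GeometryParams()


@pytest.fixture(scope="session")
def default_mask():
    return mask_array(default_mask_spec())


@pytest.fixture(scope="session")
def showcase():
    """(complex, expected matrix) of the three-residue miniature pocket."""
    return make_showcase_complex()


@pytest.fixture(scope="session")
def showcase_matrix(showcase):
    cx, _ = showcase
    return build_matrix(cx)


def _block(cells: dict, key=("A", 1, "", "ALA"), generic=None) -> ResidueBlock:
    counts = np.zeros((N_ROWS, N_COLS), dtype=np.int64)
    for (row, col), v in cells.items():
        counts[ROW_INDEX[row], COL_INDEX[col]] = v
    return ResidueBlock(counts=counts, residue_key=tuple(key),
                        generic_number=generic)


def _random_matrix(rng: np.random.Generator, n_res: int = 3,
                   generic_numbers=None, complex_id: str = "rand",
                   fingerprint: str = "testparams") -> InteractionMatrix:
    """Random matrix with counts only in incrementable cells."""
    mask = mask_array(default_mask_spec())
    blocks = []
    for i in range(n_res):
        counts = rng.integers(0, 3, size=(N_ROWS, N_COLS)) * mask
        blocks.append(ResidueBlock(
            counts=counts.astype(np.int64),
            residue_key=("A", i + 1, "", "ALA"),
            generic_number=None if generic_numbers is None
            else generic_numbers[i]))
    return InteractionMatrix(blocks=blocks, complex_id=complex_id,
                             params_fingerprint=fingerprint)


@pytest.fixture
def make_block():
    return _block


@pytest.fixture
def make_random_matrix():
    return _random_matrix
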