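import random

import numpy as np
import pytest

from fitchclad import (
    CharacterMatrix,
    MISSING,
    Tree,
    bundled_matrix,
    branch_and_bound,
)

#: display root used by the bundled study (the Haglinae outgroup)
OUTGROUP = "Euhagla saurensis"


@pytest.fixture(scope="session")
def matrix():
    return bundled_matrix()


@pytest.fixture(scope="session")
def mpts(matrix):
    """Exact optimal tree set of the bundled matrix (shared across tests)."""
    return branch_and_bound(matrix)


@pytest.fixture
def quartet():
    """((a,b),(c,d)) as an unrooted tree."""
    return Tree.from_newick("((a,b),(c,d));")


def random_matrix(
    rng: random.Random,
    n_taxa: int,
    n_chars: int,
    n_states: int = 4,
    missing_frac: float = 0.0,
) -> CharacterMatrix:
    """Uniform random matrix (no tree structure) for oracle comparisons."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    cells = np.array(
        [
            [
                MISSING
                if rng.random() < missing_frac
                else rng.randrange(n_states)
                for _ in range(n_chars)
            ]
            for _ in range(n_taxa)
        ],
        dtype=np.int8,
    )
    return CharacterMatrix(taxa, cells)
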