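import numpy as np
import pytest

from cytosym.alignment import PartitionedAlignment
from cytosym.synthetic import SyntheticParams, simulate_dataset


@pytest.fixture(scope="session")
def small_params():
    """A small, fast synthetic world shared by read-only tests."""
    return SyntheticParams(n_strains=8, mt_length=600, wol_length=1200,
                           nuclear_length=300, seed=25)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_alignment(rows: dict[str, str], site_class="noncoding"):
    """Build a PartitionedAlignment from A/C/G/T strings."""
    from cytosym.substitution import encode_sequence

    ids = list(rows)
    matrix = np.vstack([encode_sequence(rows[s]) for s in ids])
    L = matrix.shape[1]
    return PartitionedAlignment(
        ids=ids, matrix=matrix,
        site_class=np.full(L, site_class, dtype=object),
        coords=np.arange(1, L + 1))
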