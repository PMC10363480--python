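import numpy as np
import pytest

from peptarget import packaged_grid, packaged_study_peptides
from peptarget.scales import ALPHABET


@pytest.fixture(scope="session")
def library():
    """The packaged synthetic study-peptide panel (17 records)."""
    return packaged_study_peptides()


@pytest.fixture(scope="session")
def grid():
    """The packaged transcribed targeting-outcome grid."""
    return packaged_grid()


def random_sequences(n, min_len, max_len, seed):
    """Deterministic random peptide sequences over the 20-letter alphabet."""
    rng = np.random.default_rng(seed)
    residues = list(ALPHABET)
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(residues, size=length)))
    return out
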