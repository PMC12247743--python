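import random

import numpy as np
import pytest

from graphtcr import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_peptides(n, max_len=15, min_len=1, seed=0):
    r = random.Random(seed)
    return ["".join(r.choices(AMINO_ACIDS, k=r.randint(min_len, max_len)))
            for _ in range(n)]


@pytest.fixture
def small_repertoire():
    """4 epitopes x 40 TCRs with fully faithful planted 3-mers."""
    from graphtcr import SimulationConfig, simulate_repertoire
    return simulate_repertoire(SimulationConfig(
        n_epitopes=4, tcrs_per_epitope=40, motif_fidelity=1.0, seed=11))
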