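import numpy as np
import pandas as pd
import pytest

from modscreen.config import SimConfig


@pytest.fixture
def small_screens_cfg():
    return SimConfig(seed=11, n_genes=400, n_screens=3,
                     frac_shared_hits=0.05, frac_specific_hits=0.02)


@pytest.fixture
def tiny_library():
    """Four constructs, two genes plus two non-targeting controls."""
    return pd.DataFrame(
        {
            "construct_id": ["C1", "C2", "C3", "C4"],
            "guide_a_seq": ["ACGTACGTAC", "TTTTGGGGCC", "GATCGATCGA", "CCCCAAAATT"],
            "guide_b_seq": ["TGCATGCATG", "AAAACCCCGG", "CTAGCTAGCT", "GGGGTTTTAA"],
            "target_gene": ["GENE1", "GENE2", "non-targeting", "non-targeting"],
            "is_nt": [False, False, True, True],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
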