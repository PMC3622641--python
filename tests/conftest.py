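import numpy as np
import pytest

import seqgsea as sg


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset with planted DE and DS effects."""
    cfg = sg.SimConfig(
        n_genes=150,
        m_A=5,
        m_B=5,
        de_fraction=0.1,
        ds_fraction=0.1,
        seed=11,
        geneset_spec=sg.GeneSetSpec(set_size=12, n_null=8),
    )
    cd, truth, collection = sg.simulate(cfg)
    cd = sg.attach_size_factors(cd)
    return cd, truth, collection


@pytest.fixture(scope="session")
def small_scored(small_dataset):
    """Observed + permutation DE/DS scores on the small dataset (40 shuffles)."""
    cd, _, _ = small_dataset
    return sg.compute_scores(cd, n_perm=40, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
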