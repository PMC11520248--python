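import numpy as np
import pytest

import ureafold as uf
from ureafold.synth import generate_normalized_dataset


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Exact-model (S, F, D, truth) triplet at the default study conditions."""
    cfg = uf.default_config(seed=11, noise=False)
    return generate_normalized_dataset(cfg)


@pytest.fixture(scope="session")
def trp_pocket():
    """Synthetic Trp-pocket assembly (built once; SASA contexts are slow-ish)."""
    structure, selection = uf.build_synthetic_trp_pocket()
    return structure, selection


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
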