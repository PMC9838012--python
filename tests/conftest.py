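import numpy as np
import pytest
import scipy.sparse as sp

from mrngcn.data_model import GeneIndex, NodeIndex, RunConfig
from mrngcn.synthetic import SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small synthetic instance for structural / smoke tests."""
    return generate(SynthConfig(n_genes=40, n_outlying=20, n_mirna=10,
                                n_contexts=2, samples_per_context=8,
                                frac_positive=0.25, label_fraction=0.5,
                                seed=7))


@pytest.fixture
def tiny_config():
    return RunConfig(epochs=3, cv_folds=2, hidden_dims=(16, 8),
                     pretrain_epochs=5, conv1d_hidden=4, mlp_hidden=(8, 4),
                     seed=3)


@pytest.fixture
def gene_index():
    return GeneIndex(["g1", "g2", "g3", "g4"])


@pytest.fixture
def random_binary(rng):
    def make(shape, p=0.3, symmetric=False):
        A = (rng.random(shape) < p).astype(float)
        if symmetric:
            A = np.triu(A, k=1)
            A = A + A.T
        return sp.csr_matrix(A)

    return make
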