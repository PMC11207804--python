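import numpy as np
import pytest

from admetgnn.molgraph import GraphBatch


def random_graph(rng, n, f_in):
    """A random symmetric 0/1 adjacency with self-loops plus node features."""
    H = rng.normal(size=(n, f_in)).astype(np.float32)
    A = (rng.random((n, n)) < 0.5).astype(np.float32)
    A = np.maximum(A, A.T)
    A[np.arange(n), np.arange(n)] = 1.0
    return H, A


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def diverse_smiles():
    """Small molecules covering all four bond classes, charges and chirality."""
    return [
        "C", "CC", "CCO", "C#N", "CC#C", "C=C", "CC(=O)O", "c1ccccc1",
        "Cc1ccccc1", "c1ccc2ccccc2c1", "C[C@H](N)C(=O)O", "[NH4+]",
        "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "O=C(O)c1ccccc1OC(C)=O", "C1CC1",
        "N#Cc1ccccc1", "CCOC(=O)CC", "[O-]C(=O)C", "FC(F)(F)c1ccccc1",
    ]


@pytest.fixture(scope="session")
def benzene_batch():
    return GraphBatch.from_smiles(["c1ccccc1", "CC#C", "C=CCO"], n_max=8)
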