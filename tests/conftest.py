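import numpy as np
import pytest

from aoncb import DiscreteJumpModel, NeuronParams


@pytest.fixture
def params():
    return NeuronParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_discrete_model(rng, n_neurons=1, max_atoms=6, wmax=0.5, labels=None):
    """Random discrete-atom jump model with mixed e/i components."""
    n_atoms = rng.integers(2, max_atoms + 1)
    We = rng.uniform(0, wmax, (n_atoms, n_neurons))
    Wi = rng.uniform(0, wmax, (n_atoms, n_neurons))
    # sparsify but keep every atom nonempty
    mask = rng.random((n_atoms, 2 * n_neurons)) < 0.35
    We[mask[:, :n_neurons]] = 0.0
    Wi[mask[:, n_neurons:]] = 0.0
    tot = We.sum(axis=1) + Wi.sum(axis=1)
    We[tot == 0, 0] = rng.uniform(0.01, wmax, int((tot == 0).sum()))
    probs = rng.dirichlet(np.ones(n_atoms))
    rate = float(rng.uniform(500.0, 4000.0))
    return DiscreteJumpModel(
        labels=tuple(labels) if labels else tuple(range(n_neurons)),
        rate=rate, We=We, Wi=Wi, probs=probs,
    )
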