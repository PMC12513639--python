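import numpy as np
import pytest

import fedharmony as fh
from fedharmony import _kernels as kern
from fedharmony.centralized import HarmonyState


@pytest.fixture(scope="session")
def small_scenario():
    """3 sites x 120 cells, 3 cell types, moderate batch shift."""
    cfg = fh.ScenarioConfig(
        n_sites=3,
        cells_per_site=(120, 120, 120),
        n_celltypes=3,
        n_features=30,
        batch_shift_scale=4.0,
        noise_sd=1.0,
        seed=11,
    )
    return fh.generate_scenario(cfg)


@pytest.fixture(scope="session")
def small_embeddings(small_scenario):
    _, Z_sites = fh.federated_pca(small_scenario.matrices, d=10)
    return Z_sites


def random_harmony_state(rng, d=3, N=12, K=4, B=2):
    """A valid random HarmonyState with unit-norm Z and Y columns."""
    Z = kern.l2_normalize_columns(rng.normal(size=(d, N)))
    batches = rng.integers(0, B, size=N)
    batches[:B] = np.arange(B)  # every batch occupied
    phi = np.zeros((B, N))
    phi[batches, np.arange(N)] = 1.0
    R = rng.random(size=(K, N)) + 1e-3
    R /= R.sum(axis=0, keepdims=True)
    Y = kern.l2_normalize_columns(rng.normal(size=(d, K)))
    Pr_b = phi.sum(axis=1) / N
    O = R @ phi.T
    E = np.outer(O.sum(axis=1), Pr_b)
    return HarmonyState(Z.copy(), Z.copy(), phi, R, Y, O, E, Pr_b)
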