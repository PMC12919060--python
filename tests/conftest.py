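import numpy as np
import pytest

import longisift as L
from longisift.phantom import PhantomConfig


@pytest.fixture(scope="session")
def unit_grid():
    """4^3 grid of unit voxels with centres at integer coordinates."""
    return L.VoxelGrid(shape=(4, 4, 4))


@pytest.fixture(scope="session")
def noiseless_config():
    return PhantomConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def model1_pair(noiseless_config):
    return L.build_model(1, noiseless_config)


@pytest.fixture(scope="session")
def removal_pair():
    """Isolated bundle fully present at TP1 and absent at TP2."""
    return L.build_isolated_pair(1000, 0)


@pytest.fixture(scope="session")
def removal_fit(removal_pair):
    """Deeply converged unbiased fit on the removal phantom, negligible
    regularisation and no trajectory jitter (analytic conditions)."""
    tract = L.synthesize_tractogram(removal_pair, n_streamlines=400,
                                    fp_fraction=0.0, jitter=0.0, seed=3)
    traversal = L.compute_traversal(tract, removal_pair.fixels)
    unbiased = L.fit_unbiased(tract, traversal, removal_pair.fixels,
                              lambda_abs=1e-6, max_sweeps=3000, tol=1e-13)
    return tract, traversal, unbiased


def tiny_instance(seed, n_streamlines=3, n_fixels=4, lambda_=0.1):
    """Random dense small absolute-fit instance for oracle comparisons."""
    from scipy import sparse

    rng = np.random.default_rng(seed)
    lengths = rng.uniform(0.5, 1.5, size=(n_streamlines, n_fixels))
    lengths[rng.uniform(size=lengths.shape) < 0.3] = 0.0
    # every streamline traverses something, every fixel is traversed
    for s in range(n_streamlines):
        if lengths[s].sum() == 0:
            lengths[s, rng.integers(n_fixels)] = 1.0
    for f in range(n_fixels):
        if lengths[:, f].sum() == 0:
            lengths[rng.integers(n_streamlines), f] = 1.0
    traversal = L.TraversalMatrix(sparse.csr_matrix(lengths),
                                  np.zeros(n_streamlines))
    grid = L.VoxelGrid(shape=(n_fixels, 1, 1))
    fixels = L.FixelSet(
        grid=grid,
        voxels=np.stack([np.arange(n_fixels),
                         np.zeros(n_fixels, dtype=int),
                         np.zeros(n_fixels, dtype=int)], axis=1),
        directions=np.tile([1.0, 0.0, 0.0], (n_fixels, 1)),
        weights=rng.uniform(0.5, 1.5, size=n_fixels),
        fd=rng.uniform(0.5, 2.0, size=(n_fixels, 1)),
        max_per_voxel=1,
    )
    A = L.compute_scale_A(fixels, traversal)
    reg = L.RegularisationSpec(lambda_=lambda_, A=A)
    return fixels, traversal, reg
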