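import numpy as np
import pytest

from spectclust import (
    BasisConfig,
    CurveDataset,
    PhantomSpec,
    build_design_matrix,
    default_energy_grid,
    make_phantom,
)


@pytest.fixture
def energies():
    return default_energy_grid(21)


@pytest.fixture
def design(energies):
    return build_design_matrix(energies, BasisConfig())


@pytest.fixture
def poly_design(energies):
    return build_design_matrix(energies, BasisConfig(kind="polynomial", degree=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_dataset(rng, energies):
    """Small unstructured dataset: 40 voxels x 21 energies."""
    n = 40
    return CurveDataset(
        coords=rng.normal(size=(n, 3)) * 5,
        curves=rng.normal(size=(n, energies.size)) * 30 + 50,
        energies=energies,
    )


@pytest.fixture(scope="session")
def small_phantom():
    """A compact phantom for pipeline-level tests: 16x16x3 voxels, K=3."""
    spec = PhantomSpec(shape=(16, 16, 3), K_true=3, tumor_cluster=3, seed=7)
    return spec, make_phantom(spec)
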