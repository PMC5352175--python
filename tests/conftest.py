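import numpy as np
import pytest

from dectgrade import MaterialBasis, PhantomConfig


@pytest.fixture(scope="session")
def basis() -> MaterialBasis:
    return MaterialBasis()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160913)


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    """Small, quick phantom used across imaging-stage tests."""
    return PhantomConfig(grid_shape=(24, 24, 24), nodule_radius=8.0, seed=7)


def random_locus_voxels(
    basis: MaterialBasis, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random unenhanced compositions on the air-fat-soft locus plus iodine.

    Returns (fractions (n,3), concentrations (n,), expected iodine HU (n,)).
    Compositions mix adjacent basis materials only, i.e. they lie on the
    locus the decomposition projects onto.
    """
    seg = rng.integers(0, 2, size=n)
    s = rng.uniform(0.0, 1.0, size=n)
    fractions = np.zeros((n, 3))
    first = seg == 0
    fractions[first, 0] = 1.0 - s[first]
    fractions[first, 1] = s[first]
    fractions[~first, 1] = 1.0 - s[~first]
    fractions[~first, 2] = s[~first]
    conc = rng.uniform(0.0, 5.0, size=n)
    return fractions, conc, conc * basis.iodine_unit_hu_high
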