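import numpy as np
import pytest

from smnpeak import (CohortConfig, GridSpec, SourceSpec, Volume4D,
                     default_smn_source)


@pytest.fixture(scope="session")
def tiny_grid() -> GridSpec:
    """13^3 grid at 6 mm, symmetric about x = y = z = 0."""
    return GridSpec(shape=(13, 13, 13), voxel_size_mm=(6.0, 6.0, 6.0),
                    origin_mm=(-36.0, -36.0, -36.0))


@pytest.fixture(scope="session")
def tiny_cohort(tiny_grid) -> CohortConfig:
    """2 subjects x 2 visits x 1 condition on the tiny grid, short runs."""
    smn = SourceSpec("SMN", blobs=(((-18.0, 0.0, 12.0), 14.0, 1.0),
                                   ((18.0, 0.0, 12.0), 14.0, 1.0)))
    return CohortConfig(
        n_subjects=2, visits=(("V1", "scannerA"), ("V2", "scannerA")),
        conditions=("EO",), n_volumes=16, grid=tiny_grid, sources=(smn,),
        sigma_between_mm=3.0, sigma_within_mm=2.0, noise_sd=0.2, seed=7)


@pytest.fixture(scope="session")
def reduced_cohort() -> CohortConfig:
    """Reduced-scale realistic cohort: 6 mm MNI-like grid, 80 volumes."""
    from smnpeak import REDUCED_GRID
    return CohortConfig(
        n_subjects=2, visits=(("V1", "scannerA"), ("V2", "scannerA")),
        conditions=("EO",), n_volumes=80, grid=REDUCED_GRID,
        sigma_between_mm=6.0, sigma_within_mm=3.0, noise_sd=0.2, seed=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_volume(rng, shape=(8, 8, 8), t=20) -> Volume4D:
    return Volume4D(rng.standard_normal((*shape, t)), np.eye(4) * 1.0)
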