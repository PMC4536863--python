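import numpy as np
import pytest

from msapop import (
    BandMatrix,
    SampleMetadata,
    SimulationConfig,
    generate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_bands():
    """2 bands x 3 samples covering all four lane patterns plus missing."""
    return BandMatrix(
        band_ids=["b1", "b2"],
        sample_ids=["s1", "s2", "s3"],
        h=[[1, 0, 1], [0, 1, -1]],
        m=[[1, 1, 0], [0, 1, 1]],
    )


@pytest.fixture
def tiny_metadata():
    return SampleMetadata.from_records(
        ["s1", "s2", "s3"], ["north", "north", "south"]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """3 populations x 5 samples x 80 sites, moderate divergence."""
    config = SimulationConfig(
        n_populations=3, n_per_population=5, n_sites=80,
        divergence=0.3, band_error=0.02, seed=11,
    )
    return generate(config)


def random_band_matrix(rng, n_bands=12, n_samples=6, missing_frac=0.1,
                       assay="MSAP", te_family=None):
    h = rng.integers(0, 2, size=(n_bands, n_samples)).astype(np.int8)
    m = rng.integers(0, 2, size=(n_bands, n_samples)).astype(np.int8)
    if missing_frac:
        h[rng.random((n_bands, n_samples)) < missing_frac] = -1
        m[rng.random((n_bands, n_samples)) < missing_frac] = -1
    return BandMatrix(
        band_ids=[f"b{i}" for i in range(n_bands)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        h=h, m=m, assay=assay, te_family=te_family,
    )
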