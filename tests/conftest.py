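import warnings

import numpy as np
import pandas as pd
import pytest

from nircarb import (
    NoiseConfig,
    SpectraSet,
    build_default_library,
    generate_dataset,
    wavelength_grid,
)
from nircarb.synthetic_data import design


@pytest.fixture(scope="session")
def grid():
    return wavelength_grid(1100, 2500, 8)


@pytest.fixture(scope="session")
def library(grid):
    return build_default_library(grid)


@pytest.fixture(scope="session")
def small_dataset(library):
    """Two-tissue dataset, 20 samples each, default noise, fixed seed."""
    designs = [
        design("root", 9.64, 0.25, 0.30, 0.01, n_samples=20),
        design("trunk_phloem", 11.05, 1.03, 1.93, 0.63, n_samples=20,
               glucose_fructose_rho=0.9),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(designs, library, NoiseConfig(seed=42))


@pytest.fixture(scope="session")
def silent_dataset(library):
    """Noise-free dataset: exact Beer–Lambert spectra."""
    designs = [design("root", 9.64, 0.25, 0.30, 0.01, n_samples=15)]
    return generate_dataset(designs, library, NoiseConfig(seed=7).silent())


@pytest.fixture
def tiny_spectra(grid):
    """Hand-built 2-sample, 2-replicate SpectraSet on the full grid."""
    rng = np.random.default_rng(0)
    n = 4
    reflectance = 0.2 + 0.6 * rng.random((n, grid.size))
    metadata = pd.DataFrame(
        {
            "tissue": ["root", "root"],
            "season": ["summer", "summer"],
            "treatment": ["control", "control"],
            "side": ["not_applicable", "not_applicable"],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    return SpectraSet(
        grid=grid,
        reflectance=reflectance,
        sample_id=np.array(["s1", "s1", "s2", "s2"], dtype=object),
        replicate=np.array([0, 1, 0, 1]),
        metadata=metadata,
    )
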