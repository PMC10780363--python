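import numpy as np
import pytest

from soyspec import (
    FULL_GRID,
    GeneratorConfig,
    SpectrumSet,
    generate_dataset,
    savitzky_golay_smooth,
)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def dataset(default_config):
    """Default 48-sample synthetic dataset (spectra + layered LNC)."""
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def smoothed(dataset):
    spectra, _ = dataset
    return savitzky_golay_smooth(spectra)


@pytest.fixture(scope="session")
def lnc(dataset):
    return dataset[1]


def random_spectra(n_samples: int, seed: int) -> SpectrumSet:
    """Uniform-random reflectance on the full instrument grid."""
    rng = np.random.default_rng(seed)
    refl = rng.uniform(0.05, 0.95, size=(n_samples, FULL_GRID.size))
    return SpectrumSet(
        FULL_GRID.copy(), refl, [f"R{k:02d}" for k in range(n_samples)]
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One fast full-pipeline run (coarse 50 nm search stride), reused by
    grid-shape, manifest and IO tests."""
    import pandas as pd

    from soyspec import RunConfig, run_all

    cfg = RunConfig(seed=0, search_stride=50)
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    run_all(cfg, outdir)
    return outdir
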