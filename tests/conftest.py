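import numpy as np
import pytest

from ionrank.io import CentroidedDataset, CentroidedSpectrum
from ionrank.simulate import SimulationConfig, generate_dataset, toy_database


@pytest.fixture(scope="session")
def toy_db():
    return toy_database(12, seed=7)


@pytest.fixture(scope="session")
def clean_dataset(toy_db):
    """Small noisy dataset with 5 planted ions (fixed seed)."""
    cfg = SimulationConfig(
        seed=11,
        grid_shape=(16, 16),
        n_molecules=5,
        database=toy_db,
        noise_peaks_per_pixel=15,
        snr=10,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset(toy_db):
    """Noise-free, jitter-free dataset: the infinite-SNR limit."""
    cfg = SimulationConfig(
        seed=5,
        grid_shape=(12, 12),
        n_molecules=4,
        database=toy_db,
        jitter_ppm=0.0,
        noise_peaks_per_pixel=0,
        snr=np.inf,
        spatial_pattern="region",
    )
    return generate_dataset(cfg)


def grid_dataset(values_per_pixel, shape=(2, 2), **kwargs):
    """Build a dataset from explicit per-pixel (mz, intensity) peak lists.

    ``values_per_pixel`` is a list of (mz_list, intensity_list), row-major.
    """
    rows, cols = shape
    assert len(values_per_pixel) == rows * cols
    spectra = {
        i: CentroidedSpectrum(np.asarray(mz, float), np.asarray(inten, float))
        for i, (mz, inten) in enumerate(values_per_pixel)
    }
    coords = np.array([(i % cols, i // cols) for i in range(rows * cols)])
    return CentroidedDataset(spectra=spectra, coords=coords, **kwargs)
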