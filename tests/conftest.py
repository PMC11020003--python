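import numpy as np
import pytest

from drsmargin.io import RawSpectrum, SpectrumSet
from drsmargin.preprocessing import WavelengthGrid
from drsmargin.synthetic import (
    SyntheticDatasetSpec,
    TissueOpticsParams,
    generate_dataset,
    generate_spectrum,
)

ANALYSIS_GRID = WavelengthGrid()  # 450-1000 nm, 1922 points


@pytest.fixture(scope="session")
def analysis_grid() -> WavelengthGrid:
    return ANALYSIS_GRID


@pytest.fixture(scope="session")
def small_dataset() -> SpectrumSet:
    """10 patients x 2 classes x 15 spectra, default contrast, moderate noise."""
    return generate_dataset(
        SyntheticDatasetSpec(n_patients=10, spectra_per_class_per_patient=15, seed=42)
    )


def spectrum_with_means(means) -> SpectrumSet:
    """Tiny set whose per-spectrum mean intensities equal ``means``."""
    wl = np.array([500.0, 600.0])
    return SpectrumSet(
        [RawSpectrum(wl, np.array([m, m], dtype=float)) for m in means]
    )


def noise_free_spectrum(
    bvf: float = 0.03, sat: float = 0.6, grid: WavelengthGrid | None = None
) -> RawSpectrum:
    params = TissueOpticsParams(
        blood_volume_fraction=bvf, hb_saturation=sat, noise_sd=0.0
    )
    return generate_spectrum(params, grid or ANALYSIS_GRID, rng=0)
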