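"""Haemoglobin absorption curves used by the spectrum generator and unmixer.

The bundled table ``data/hemoglobin_extinction_synthetic.csv`` holds synthetic
whole-blood absorption coefficients (mm^-1) for fully oxygenated and fully
deoxygenated blood on a 1 nm grid, 440-1010 nm. It is a physically motivated
approximation (see ``scripts/build_extinction_table.py``), not a published
reference table; all that downstream code relies on is the qualitative band
structure (oxy double peak at 542/577 nm, deoxy single peak at 555 nm,
near-infrared crossover near 800 nm).
"""

from functools import lru_cache
from importlib import resources

import numpy as np

from .errors import CoverageError

__all__ = ["extinction_support", "hemoglobin_extinction"]


@lru_cache(maxsize=1)
def _table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ref = resources.files("drsmargin").joinpath(
        "data/hemoglobin_extinction_synthetic.csv"
    )
    with ref.open("rb") as fh:
        data = np.loadtxt(fh, delimiter=",", skiprows=2)
    return data[:, 0], data[:, 1], data[:, 2]


def extinction_support() -> tuple[float, float]:
    """Wavelength range (nm) over which absorption curves are defined."""
    wl, _, _ = _table()
    return float(wl[0]), float(wl[-1])


def hemoglobin_extinction(wavelengths_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Absorption coefficients of oxygenated and deoxygenated whole blood.

    Parameters
    ----------
    wavelengths_nm
        Wavelengths (nm) at which to evaluate; must lie inside the table's
        support.

    Returns
    -------
    (mu_a_oxy, mu_a_deoxy)
        Arrays of whole-blood absorption coefficients in mm^-1.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    lo, hi = extinction_support()
    if wl.size and (wl.min() < lo or wl.max() > hi):
        raise CoverageError(
            f"requested wavelengths {wl.min():.1f}-{wl.max():.1f} nm exceed the "
            f"absorption table support {lo:.1f}-{hi:.1f} nm"
        )
    grid, oxy, deoxy = _table()
    return np.interp(wl, grid, oxy), np.interp(wl, grid, deoxy)
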