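"""Resampling onto the analysis grid, SNV normalisation, MAD outlier rejection.

The processing chain applied to a set of raw acquisitions is

    calibrate (white/dark)  ->  resample to grid  ->  reject outliers  ->  SNV

Outliers are judged on calibrated physical reflectance, before SNV erases
per-spectrum scale; the per-spectrum "residual" driving the rule is the mean
calibrated intensity over the grid, so whole aberrant acquisitions (air gaps,
saturation) are removed rather than single wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, DegenerateInputError
from .io import RawSpectrum, ReferenceSet, SpectrumSet, compute_reflectance

__all__ = [
    "WavelengthGrid",
    "ProcessedSpectrum",
    "OutlierReport",
    "resample_to_grid",
    "snv_normalize",
    "detect_outliers",
    "preprocess_set",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Equally spaced analysis grid, endpoints inclusive.

    Defaults give 1922 samples over 450-1000 nm (spacing ~0.286 nm).
    """

    start: float = 450.0
    stop: float = 1000.0
    n_points: int = 1922

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError("grid start must be below stop")
        if self.n_points < 2:
            raise ValueError("grid needs at least two points")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)

    @property
    def step(self) -> float:
        return (self.stop - self.start) / (self.n_points - 1)


@dataclass
class SpectrumProvenance:
    patient_id: str = ""
    label: str = "unknown"
    acquisition_index: int = 0


@dataclass
class ProcessedSpectrum:
    """A spectrum on the analysis grid, optionally SNV-normalised.

    After SNV the values have per-spectrum mean 0 and sample standard
    deviation 1 (divisor n-1); ``pre_snv_values`` retains the calibrated
    reflectance for consumers that need physical scale (e.g. the haemoglobin
    saturation unmixer).
    """

    grid: WavelengthGrid
    values: np.ndarray
    snv_applied: bool = False
    source: SpectrumProvenance = field(default_factory=SpectrumProvenance)
    pre_snv_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.grid.n_points:
            raise ValueError(
                f"values length {self.values.size} != grid points {self.grid.n_points}"
            )

    @property
    def patient_id(self) -> str:
        return self.source.patient_id

    @property
    def label(self) -> str:
        return self.source.label

    @property
    def acquisition_index(self) -> int:
        return self.source.acquisition_index


@dataclass
class OutlierReport:
    """Per-spectrum residual diagnostics from the median/MAD rule.

    A spectrum is flagged iff ``|residual - median| > threshold_factor * MAD``
    (strict inequality, unscaled MAD). The 25th/75th percentiles are reported
    for diagnostics and play no role in the flags.
    """

    residuals: np.ndarray
    median_residual: float
    q25: float
    q75: float
    mad: float
    threshold_factor: float
    flags: np.ndarray

    def summary_table(self) -> str:
        lines = [
            f"# median={self.median_residual:.6g} mad={self.mad:.6g} "
            f"q25={self.q25:.6g} q75={self.q75:.6g} factor={self.threshold_factor:g}",
            "index\tresidual\tflagged",
        ]
        for i, (r, f) in enumerate(zip(self.residuals, self.flags)):
            lines.append(f"{i}\t{r:.9g}\t{int(f)}")
        return "\n".join(lines) + "\n"


def resample_to_grid(spectrum: RawSpectrum, grid: WavelengthGrid) -> ProcessedSpectrum:
    """Linearly interpolate a spectrum onto the analysis grid (no extrapolation)."""
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if lo > grid.start or hi < grid.stop:
        missing = []
        if lo > grid.start:
            missing.append(f"{grid.start:.1f}-{lo:.1f} nm")
        if hi < grid.stop:
            missing.append(f"{hi:.1f}-{grid.stop:.1f} nm")
        raise CoverageError(
            "spectrum does not cover the analysis grid; missing "
            + " and ".join(missing)
        )
    values = np.interp(grid.wavelengths, spectrum.wavelengths, spectrum.intensities)
    return ProcessedSpectrum(
        grid=grid,
        values=values,
        snv_applied=False,
        source=SpectrumProvenance(
            spectrum.patient_id, spectrum.label, spectrum.acquisition_index
        ),
    )


def snv_normalize(spectrum: ProcessedSpectrum) -> ProcessedSpectrum:
    """Standard normal variate: remove the per-spectrum mean, scale to unit sd."""
    v = spectrum.values
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("zero-variance spectrum cannot be SNV-normalised")
    return ProcessedSpectrum(
        grid=spectrum.grid,
        values=(v - v.mean()) / sd,
        snv_applied=True,
        source=spectrum.source,
        pre_snv_values=v.copy(),
    )


def detect_outliers(sset: SpectrumSet, threshold_factor: float = 1.5) -> OutlierReport:
    """Flag aberrant spectra by the median/MAD rule on mean intensity.

    residual_i = mean intensity of spectrum i; MAD = median |r - median(r)|,
    unscaled. Flag iff deviation from the median strictly exceeds
    ``threshold_factor * MAD``.
    """
    if len(sset) < 3:
        raise ValueError("outlier detection needs at least 3 spectra")
    mat = sset.intensity_matrix()
    residuals = mat.mean(axis=1)
    med = float(np.median(residuals))
    mad = float(np.median(np.abs(residuals - med)))
    q25, q75 = (float(q) for q in np.percentile(residuals, [25, 75]))
    flags = np.abs(residuals - med) > threshold_factor * mad
    return OutlierReport(
        residuals=residuals,
        median_residual=med,
        q25=q25,
        q75=q75,
        mad=mad,
        threshold_factor=threshold_factor,
        flags=flags,
    )


def preprocess_set(
    sset: SpectrumSet,
    refs: ReferenceSet | None = None,
    grid: WavelengthGrid | None = None,
    mad_factor: float = 1.5,
) -> tuple[SpectrumSet, OutlierReport]:
    """Full chain: calibrate -> resample -> reject outliers -> SNV.

    ``refs=None`` means the set already holds calibrated reflectance.
    Returns the cleaned, SNV-normalised set and the outlier report (whose
    flags refer to the resampled, pre-rejection set).
    """
    if len(sset) == 0:
        raise ValueError("empty spectrum set")
    grid = grid or WavelengthGrid()
    calibrated = (
        [compute_reflectance(s, refs) for s in sset] if refs is not None else list(sset)
    )
    resampled = SpectrumSet(
        [resample_to_grid(s, grid) for s in calibrated], dict(sset.metadata)
    )
    report = detect_outliers(resampled, threshold_factor=mad_factor)
    kept = resampled.subset(~report.flags)
    out = SpectrumSet([snv_normalize(s) for s in kept], dict(sset.metadata))
    out.metadata["grid"] = grid
    out.metadata["snv_applied"] = True
    return out, report
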