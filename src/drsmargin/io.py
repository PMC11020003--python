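"""Spectra containers, the DRSSPEC/1 columnar text format, and white/dark calibration.

File format (versioned magic ``DRSSPEC/1``)::

    # DRSSPEC/1
    # kind: raw
    # spectrum<TAB>0<TAB>patient_id=P001<TAB>label=tumour<TAB>acquisition_index=0
    # spectrum<TAB>1<TAB>...
    wavelength_nm<TAB>s0000<TAB>s0001<TAB>...
    450.000000<TAB>0.812345<TAB>...

One shared, strictly ascending wavelength column; one intensity column per
spectrum; per-spectrum metadata in the leading comment block. Human
inspectable and diff-able, which is the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import CalibrationError, FormatError

MAGIC = "DRSSPEC/1"
VALID_LABELS = ("normal", "tumour", "unknown")

__all__ = [
    "MAGIC",
    "VALID_LABELS",
    "RawSpectrum",
    "ReferenceSet",
    "SpectrumSet",
    "compute_reflectance",
    "read_spectra",
    "write_spectra",
]


@dataclass
class RawSpectrum:
    """One acquired spectrum: per-wavelength intensity in detector units.

    ``wavelengths`` must be strictly ascending and the same length as
    ``intensities``; ``label`` is one of :data:`VALID_LABELS`.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    patient_id: str = ""
    label: str = "unknown"
    acquisition_index: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError(
                f"wavelengths ({self.wavelengths.size}) and intensities "
                f"({self.intensities.size}) differ in length"
            )
        if self.wavelengths.size < 2:
            raise ValueError("a spectrum needs at least two sample points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"label {self.label!r} not recognised; accepted tokens: "
                + ", ".join(VALID_LABELS)
            )


@dataclass
class ReferenceSet:
    """White reflectance standard and dark-field reading on one wavelength axis."""

    white: RawSpectrum
    dark: RawSpectrum

    def __post_init__(self) -> None:
        if not np.array_equal(self.white.wavelengths, self.dark.wavelengths):
            raise ValueError("white and dark references must share one wavelength axis")
        if np.any(self.white.intensities - self.dark.intensities <= 0):
            raise CalibrationError(
                "white - dark must be positive at every wavelength"
            )


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing provenance metadata.

    Members may be :class:`RawSpectrum` or
    :class:`~drsmargin.preprocessing.ProcessedSpectrum`; the set is the unit
    of outlier rejection and of patient-wise cross-validation splitting.
    """

    spectra: list
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator:
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.spectra])

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([s.patient_id for s in self.spectra])

    def intensity_matrix(self) -> np.ndarray:
        """Stack member intensities; requires one shared wavelength axis."""
        if not self.spectra:
            raise ValueError("empty spectrum set")
        axes = [self._axis(s) for s in self.spectra]
        for a in axes[1:]:
            if not np.array_equal(a, axes[0]):
                raise ValueError("spectra do not share a wavelength axis")
        return np.vstack([self._values(s) for s in self.spectra])

    def shared_axis(self) -> np.ndarray:
        mat_axis = self._axis(self.spectra[0])
        for s in self.spectra[1:]:
            if not np.array_equal(self._axis(s), mat_axis):
                raise ValueError("spectra do not share a wavelength axis")
        return mat_axis

    def subset(self, mask: np.ndarray) -> "SpectrumSet":
        keep = [s for s, m in zip(self.spectra, mask) if m]
        return SpectrumSet(keep, dict(self.metadata))

    @staticmethod
    def _axis(s) -> np.ndarray:
        return s.wavelengths if hasattr(s, "wavelengths") else s.grid.wavelengths

    @staticmethod
    def _values(s) -> np.ndarray:
        return s.intensities if hasattr(s, "intensities") else s.values


def compute_reflectance(sample: RawSpectrum, refs: ReferenceSet) -> RawSpectrum:
    """Calibrate raw counts against white/dark references.

    R(lambda) = (I - D) / (W - D). The white standard maps to 1, the dark
    reading to 0; values outside [0, 1] (noise) are kept, not clipped.
    """
    if not np.array_equal(sample.wavelengths, refs.white.wavelengths):
        raise ValueError("sample and references do not share a wavelength axis")
    denom = refs.white.intensities - refs.dark.intensities
    if np.any(denom <= 0):
        raise CalibrationError("white - dark must be positive at every wavelength")
    refl = (sample.intensities - refs.dark.intensities) / denom
    return replace(sample, intensities=refl)


def write_spectra(sset: SpectrumSet, path: str | Path) -> None:
    """Write a set in the DRSSPEC/1 text format (raw spectra only)."""
    if not sset.spectra:
        raise ValueError("refusing to write an empty spectrum set")
    axis = sset.shared_axis()
    mat = sset.intensity_matrix()
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {MAGIC}\n")
        fh.write("# kind: raw\n")
        for i, s in enumerate(sset.spectra):
            fh.write(
                f"# spectrum\t{i}\tpatient_id={s.patient_id}\t"
                f"label={s.label}\tacquisition_index={s.acquisition_index}\n"
            )
        cols = "\t".join(f"s{i:04d}" for i in range(len(sset.spectra)))
        fh.write(f"wavelength_nm\t{cols}\n")
        for j in range(axis.size):
            row = "\t".join(f"{v:.9g}" for v in mat[:, j])
            fh.write(f"{axis[j]:.6f}\t{row}\n")


def _parse_meta(line: str, lineno: int) -> dict:
    fields = line.lstrip("# ").rstrip("\n").split("\t")
    meta = {"index": int(fields[1])}
    for tok in fields[2:]:
        if "=" not in tok:
            raise FormatError(f"malformed metadata token {tok!r}", lineno)
        k, v = tok.split("=", 1)
        meta[k] = v
    label = meta.get("label", "unknown")
    if label not in VALID_LABELS:
        raise FormatError(
            f"unknown label token {label!r}; accepted tokens: "
            + ", ".join(VALID_LABELS),
            lineno,
        )
    return meta


def read_spectra(path: str | Path) -> SpectrumSet:
    """Read a DRSSPEC/1 file; raises :class:`FormatError` naming the bad line."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != f"# {MAGIC}":
        raise FormatError(f"missing magic header '# {MAGIC}'", 1)
    metas: list[dict] = []
    header_at = None
    for lineno, line in enumerate(lines[1:], start=2):
        if line.startswith("# spectrum\t"):
            metas.append(_parse_meta(line, lineno))
        elif line.startswith("#"):
            continue
        else:
            header_at = lineno
            break
    if header_at is None:
        raise FormatError("no column header found", len(lines))
    header = lines[header_at - 1].split("\t")
    n_spec = len(header) - 1
    if header[0] != "wavelength_nm" or n_spec < 1:
        raise FormatError("column header must be wavelength_nm followed by spectrum columns", header_at)
    if metas and len(metas) != n_spec:
        raise FormatError(
            f"{len(metas)} metadata lines for {n_spec} spectrum columns", header_at
        )
    wl: list[float] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[header_at:], start=header_at + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != n_spec + 1:
            raise FormatError(
                f"expected {n_spec + 1} columns, found {len(parts)}", lineno
            )
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise FormatError(str(exc), lineno) from None
        if wl and vals[0] <= wl[-1]:
            raise FormatError(
                f"wavelength {vals[0]} not strictly ascending after {wl[-1]}", lineno
            )
        wl.append(vals[0])
        rows.append(vals[1:])
    if len(wl) < 2:
        raise FormatError("need at least two sample rows", len(lines))
    mat = np.asarray(rows, dtype=float).T
    axis = np.asarray(wl, dtype=float)
    spectra = []
    for i in range(n_spec):
        meta = metas[i] if metas else {}
        spectra.append(
            RawSpectrum(
                wavelengths=axis,
                intensities=mat[i],
                patient_id=str(meta.get("patient_id", "")),
                label=str(meta.get("label", "unknown")),
                acquisition_index=int(meta.get("acquisition_index", i)),
            )
        )
    return SpectrumSet(spectra, {"source": str(path)})
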