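"""Synthetic DRS spectra and marker videos with known ground truth.

The spectrum generator emulates the contrast diffuse reflectance measures in
soft tissue: a scattering power-law baseline attenuated by haemoglobin
absorption,

    R(lambda) = A (lambda/500)^(-b) * exp(-BVF * L * [s*mu_oxy + (1-s)*mu_deoxy])
                + Gaussian noise,

where BVF is the blood volume fraction, s the haemoglobin oxygen saturation,
L an effective optical path length (mm) and mu_* the bundled whole-blood
absorption curves. Default class parameters give tumour tissue more blood and
lower saturation than normal tissue — separable but overlapping under noise.
Per-patient biology is emulated by multiplicative log-normal jitter on BVF
and scatter amplitude, drawn once per patient, so patient-wise
cross-validation is a meaningful test.

The video generator renders a filled green disk following a known trajectory
over a plain background, with optional occluded frames; ground truth is
returned alongside the frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from skimage.color import hsv2rgb

from .extinction import hemoglobin_extinction
from .io import RawSpectrum, ReferenceSet, SpectrumSet
from .preprocessing import WavelengthGrid

__all__ = [
    "TissueOpticsParams",
    "SyntheticDatasetSpec",
    "MarkerSceneSpec",
    "DEFAULT_CLASS_PARAMS",
    "ACQUISITION_GRID",
    "generate_spectrum",
    "generate_dataset",
    "make_reference_set",
    "reflectance_to_counts",
    "generate_marker_frames",
    "write_frames",
]


@dataclass(frozen=True)
class TissueOpticsParams:
    """Optical parameters of one tissue class.

    blood_volume_fraction and hb_saturation are dimensionless fractions;
    scatter_amplitude/scatter_power shape the power-law baseline;
    path_length is the effective photon path in mm; noise_sd is the additive
    per-wavelength Gaussian noise (reflectance units).
    """

    blood_volume_fraction: float
    hb_saturation: float
    scatter_amplitude: float = 1.0
    scatter_power: float = 1.2
    path_length: float = 5.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "blood_volume_fraction",
            "hb_saturation",
            "scatter_amplitude",
            "scatter_power",
            "path_length",
            "noise_sd",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0 <= self.blood_volume_fraction <= 1:
            raise ValueError("blood_volume_fraction must lie in [0, 1]")
        if not 0 <= self.hb_saturation <= 1:
            raise ValueError("hb_saturation must lie in [0, 1]")
        if self.scatter_amplitude <= 0:
            raise ValueError("scatter_amplitude must be positive")
        if self.scatter_power < 0:
            raise ValueError("scatter_power must be non-negative")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# Tumour: more blood, less oxygenated, slightly stronger scattering.
DEFAULT_CLASS_PARAMS: dict[str, TissueOpticsParams] = {
    "normal": TissueOpticsParams(
        blood_volume_fraction=0.015, hb_saturation=0.85,
        scatter_amplitude=1.0, scatter_power=1.2,
    ),
    "tumour": TissueOpticsParams(
        blood_volume_fraction=0.04, hb_saturation=0.60,
        scatter_amplitude=1.15, scatter_power=1.0,
    ),
}

# Raw acquisition axis: slightly wider than the 450-1000 nm analysis grid so
# resampling never extrapolates.
ACQUISITION_GRID = WavelengthGrid(start=445.0, stop=1005.0, n_points=1400)


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Study-scale description of a synthetic spectral dataset.

    Defaults mirror an acquisition protocol of ~200 spectra per tissue type
    per specimen; ``jitter_sd`` is the sigma of the per-patient log-normal
    factors on blood volume fraction and scatter amplitude.
    """

    n_patients: int
    spectra_per_class_per_patient: int = 200
    class_params: dict[str, TissueOpticsParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    jitter_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        if self.spectra_per_class_per_patient < 1:
            raise ValueError("spectra_per_class_per_patient must be at least 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


def generate_spectrum(
    params: TissueOpticsParams,
    grid: WavelengthGrid | None = None,
    rng: np.random.Generator | int | None = None,
) -> RawSpectrum:
    """Draw one reflectance spectrum from the generative model."""
    grid = grid or ACQUISITION_GRID
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    wl = grid.wavelengths
    mu_oxy, mu_deoxy = hemoglobin_extinction(wl)
    baseline = params.scatter_amplitude * (wl / 500.0) ** (-params.scatter_power)
    mu = params.hb_saturation * mu_oxy + (1 - params.hb_saturation) * mu_deoxy
    refl = baseline * np.exp(
        -params.blood_volume_fraction * params.path_length * mu
    )
    if params.noise_sd > 0:
        refl = refl + rng.normal(0.0, params.noise_sd, size=wl.size)
    return RawSpectrum(wavelengths=wl, intensities=refl)


def _jittered(p: TissueOpticsParams, f_bvf: float, f_amp: float) -> TissueOpticsParams:
    return replace(
        p,
        blood_volume_fraction=min(1.0, p.blood_volume_fraction * f_bvf),
        scatter_amplitude=p.scatter_amplitude * f_amp,
    )


def generate_dataset(
    spec: SyntheticDatasetSpec, grid: WavelengthGrid | None = None
) -> SpectrumSet:
    """Generate a labelled multi-patient reflectance dataset.

    Returns exactly ``spectra_per_class_per_patient * n_patients`` spectra per
    class; per-patient jitter factors are drawn once per patient and applied
    to every class.
    """
    grid = grid or ACQUISITION_GRID
    rng = np.random.default_rng(spec.seed)
    spectra = []
    for p in range(spec.n_patients):
        pid = f"P{p + 1:03d}"
        f_bvf, f_amp = np.exp(rng.normal(0.0, spec.jitter_sd, size=2))
        for label in sorted(spec.class_params):
            params = _jittered(spec.class_params[label], f_bvf, f_amp)
            for i in range(spec.spectra_per_class_per_patient):
                s = generate_spectrum(params, grid, rng)
                s.patient_id = pid
                s.label = label
                s.acquisition_index = i
                spectra.append(s)
    return SpectrumSet(spectra, {"seed": spec.seed, "synthetic": True})


def make_reference_set(
    grid: WavelengthGrid | None = None, seed: int = 0
) -> ReferenceSet:
    """Lamp-shaped white standard and small dark offset on the acquisition axis."""
    grid = grid or ACQUISITION_GRID
    wl = grid.wavelengths
    rng = np.random.default_rng(seed)
    # broad tungsten-like lamp shape peaking in the NIR, in detector counts
    lamp = 3.0e4 * np.exp(-0.5 * ((wl - 900.0) / 260.0) ** 2) + 4.0e3
    dark = np.full(wl.size, 120.0) + rng.normal(0.0, 1.0, wl.size)
    white = dark + lamp
    return ReferenceSet(
        white=RawSpectrum(wl, white, label="unknown"),
        dark=RawSpectrum(wl, dark, label="unknown"),
    )


def reflectance_to_counts(sset: SpectrumSet, refs: ReferenceSet) -> SpectrumSet:
    """Invert calibration: counts = D + R * (W - D), for pipeline round trips."""
    gain = refs.white.intensities - refs.dark.intensities
    out = []
    for s in sset:
        if not np.array_equal(s.wavelengths, refs.white.wavelengths):
            raise ValueError("spectrum and references do not share a wavelength axis")
        out.append(
            replace(s, intensities=refs.dark.intensities + s.intensities * gain)
        )
    return SpectrumSet(out, dict(sset.metadata))


@dataclass(frozen=True)
class MarkerSceneSpec:
    """A synthetic probe-marker video: geometry, trajectory and colours."""

    frame_width: int = 320
    frame_height: int = 240
    n_frames: int = 60
    trajectory: Literal["linear", "circular", "random_walk"] = "linear"
    trajectory_params: dict = field(default_factory=dict)
    marker_radius: int = 8
    marker_hue: float = 120.0  # degrees
    marker_saturation: float = 0.85
    marker_value: float = 0.8
    background_color: tuple[int, int, int] = (150, 110, 100)
    occluded_frames: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.marker_radius >= min(self.frame_width, self.frame_height) / 2:
            raise ValueError("marker_radius must be below half the smaller frame dimension")


def _trajectory(spec: MarkerSceneSpec, rng: np.random.Generator) -> np.ndarray:
    w, h, n, r = spec.frame_width, spec.frame_height, spec.n_frames, spec.marker_radius
    p = spec.trajectory_params
    t = np.arange(n, dtype=float)
    if spec.trajectory == "linear":
        x0, y0 = p.get("start", (r + 2.0, h / 2.0))
        vx, vy = p.get("velocity", (2.0, 0.5))
        xy = np.column_stack([x0 + vx * t, y0 + vy * t])
    elif spec.trajectory == "circular":
        cx, cy = p.get("center", (w / 2.0, h / 2.0))
        rad = p.get("radius", min(w, h) / 4.0)
        omega = p.get("angular_speed", 0.1)
        xy = np.column_stack(
            [cx + rad * np.cos(omega * t), cy + rad * np.sin(omega * t)]
        )
    elif spec.trajectory == "random_walk":
        x0, y0 = p.get("start", (w / 2.0, h / 2.0))
        step_sd = p.get("step_sd", 2.0)
        steps = rng.normal(0.0, step_sd, size=(n, 2))
        steps[0] = 0.0
        xy = np.array([x0, y0]) + np.cumsum(steps, axis=0)
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown trajectory {spec.trajectory!r}")
    # keep the whole disk inside the frame
    xy[:, 0] = np.clip(xy[:, 0], r, w - 1 - r)
    xy[:, 1] = np.clip(xy[:, 1], r, h - 1 - r)
    return xy


def marker_rgb(spec: MarkerSceneSpec) -> tuple[int, int, int]:
    rgb = hsv2rgb(
        np.array(
            [[[spec.marker_hue / 360.0, spec.marker_saturation, spec.marker_value]]]
        )
    )[0, 0]
    return tuple(int(round(255 * c)) for c in rgb)


def generate_marker_frames(
    spec: MarkerSceneSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the marker video.

    Returns ``(frames, trajectory)``: frames as uint8 RGB of shape
    (n_frames, H, W, 3) and the ground-truth (x, y) positions, one per frame.
    Frames listed in ``occluded_frames`` are rendered without the marker but
    keep their ground-truth entry.
    """
    rng = np.random.default_rng(spec.seed)
    traj = _trajectory(spec, rng)
    bg = np.array(spec.background_color, dtype=np.uint8)
    color = np.array(marker_rgb(spec), dtype=np.uint8)
    frames = np.empty(
        (spec.n_frames, spec.frame_height, spec.frame_width, 3), dtype=np.uint8
    )
    yy, xx = np.mgrid[0 : spec.frame_height, 0 : spec.frame_width]
    occluded = set(spec.occluded_frames)
    for i in range(spec.n_frames):
        frame = np.broadcast_to(
            bg, (spec.frame_height, spec.frame_width, 3)
        ).copy()
        if i not in occluded:
            cx, cy = traj[i]
            disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.marker_radius**2
            frame[disk] = color
        frames[i] = frame
    return frames, traj


def write_frames(
    frames: np.ndarray, traj: np.ndarray, outdir: str | Path
) -> list[Path]:
    """Write numbered PNG frames plus a trajectory text file (frame, x, y)."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = outdir / f"frame_{i:05d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    with (outdir / "trajectory.tsv").open("w") as fh:
        fh.write("frame\tx\ty\n")
        for i, (x, y) in enumerate(traj):
            fh.write(f"{i}\t{x:.6f}\t{y:.6f}\n")
    return paths
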