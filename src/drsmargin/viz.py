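"""Graduated probability colourmap and overlay rendering of biopsy sites.

Classification probability maps linearly from green (certain normal) to pink
(certain tumour); each sampled site is drawn as an alpha-blended filled disk
over the video frame, later sites painted over earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["GREEN", "PINK", "OverlaySite", "probability_to_color", "render_overlay"]

GREEN = (0, 255, 0)  # p = 0, certain normal
PINK = (255, 105, 180)  # p = 1, certain tumour


@dataclass(frozen=True)
class OverlaySite:
    """One optical-biopsy site: position, tumour probability and disk radius."""

    position: tuple[float, float]
    tumour_probability: float
    radius: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumour_probability <= 1.0:
            raise ValueError("tumour_probability must lie in [0, 1]")


def probability_to_color(p: float) -> tuple[int, int, int]:
    """Linear per-channel green->pink interpolation, rounded half-up."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return tuple(
        int(np.floor(g + p * (k - g) + 0.5)) for g, k in zip(GREEN, PINK)
    )


def render_overlay(
    frame: np.ndarray, sites: Sequence[OverlaySite], alpha: float = 0.6
) -> np.ndarray:
    """Return a new frame with each site blended on as a coloured disk.

    Sites are drawn in sequence order (later over earlier); the input frame
    is left unmodified. A site whose centre lies outside the frame raises.
    """
    frame = np.asarray(frame)
    h, w = frame.shape[:2]
    for s in sites:
        x, y = s.position
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"site at {s.position} outside frame bounds {w}x{h}")
    out = frame.astype(float).copy()
    yy, xx = np.mgrid[0:h, 0:w]
    for s in sites:
        x, y = s.position
        disk = (xx - x) ** 2 + (yy - y) ** 2 <= s.radius**2
        color = np.array(probability_to_color(s.tumour_probability), dtype=float)
        out[disk] = (1.0 - alpha) * out[disk] + alpha * color
    return np.floor(out + 0.5).clip(0, 255).astype(np.uint8)
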