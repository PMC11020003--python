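"""Green-marker detection by HSV thresholding and Kalman tracking of the probe tip.

Detection: each RGB frame is converted to HSV; pixels inside the configured
hue/saturation/value band (hue wraparound supported) form a mask, the largest
connected component at or above ``min_blob_area`` yields the centroid.

Tracking: a standard linear Kalman filter with constant-velocity state
(x, y, vx, vy), unit frame step, process noise q on every state component and
measurement noise r on the observed position. Missed detections advance the
prediction only; after ``max_misses`` consecutive misses the track is
declared lost and re-initialised on the next detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "HSVRange",
    "Detection",
    "TrackState",
    "segment_marker",
    "init_track",
    "kalman_step",
    "track_sequence",
]

_F = np.array(
    [[1.0, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]]
)  # constant-velocity transition, unit frame step
_H = np.array([[1.0, 0, 0, 0], [0, 1, 0, 0]])


@dataclass(frozen=True)
class HSVRange:
    """Colour gate for the marker; hue in degrees, sat/val as fractions.

    ``hue_min > hue_max`` denotes a wraparound band (e.g. reds across 0).
    """

    hue_min: float = 100.0
    hue_max: float = 140.0
    sat_min: float = 0.4
    sat_max: float = 1.0
    val_min: float = 0.3
    val_max: float = 1.0
    min_blob_area: int = 50

    def __post_init__(self) -> None:
        if self.sat_min > self.sat_max or self.val_min > self.val_max:
            raise ValueError("saturation/value bounds must satisfy min <= max")


@dataclass(frozen=True)
class Detection:
    """Marker centroid in pixel coordinates; ``valid=False`` means no marker."""

    centroid: tuple[float, float] = (float("nan"), float("nan"))
    area: float = 0.0
    valid: bool = False


def segment_marker(frame: np.ndarray, hsv: HSVRange | None = None) -> Detection:
    """Locate the marker in one RGB frame; invalid Detection if absent."""
    hsv = hsv or HSVRange()
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    hsv_img = rgb2hsv(frame)
    h = hsv_img[..., 0] * 360.0
    s = hsv_img[..., 1]
    v = hsv_img[..., 2]
    if hsv.hue_min <= hsv.hue_max:
        hue_mask = (h >= hsv.hue_min) & (h <= hsv.hue_max)
    else:  # wraparound band
        hue_mask = (h >= hsv.hue_min) | (h <= hsv.hue_max)
    mask = (
        hue_mask
        & (s >= hsv.sat_min)
        & (s <= hsv.sat_max)
        & (v >= hsv.val_min)
        & (v <= hsv.val_max)
    )
    if not mask.any():
        return Detection()
    labelled = cc_label(mask)
    best = max(regionprops(labelled), key=lambda r: r.area)
    if best.area < hsv.min_blob_area:
        return Detection()
    cy, cx = best.centroid  # regionprops returns (row, col)
    return Detection(centroid=(float(cx), float(cy)), area=float(best.area), valid=True)


@dataclass
class TrackState:
    """Kalman state: position/velocity estimate with covariance.

    ``state`` = (x, y, vx, vy) in pixels and pixels/frame; ``covariance`` is
    4x4 symmetric positive-definite. ``initialized=False`` marks frames
    before the first detection or after track loss.
    """

    state: np.ndarray = field(
        default_factory=lambda: np.full(4, np.nan)
    )
    covariance: np.ndarray = field(default_factory=lambda: np.eye(4))
    frames_since_detection: int = 0
    initialized: bool = True

    @property
    def position(self) -> tuple[float, float]:
        return float(self.state[0]), float(self.state[1])

    @property
    def velocity(self) -> tuple[float, float]:
        return float(self.state[2]), float(self.state[3])


def init_track(detection: Detection) -> TrackState:
    """Start a track at a detection: zero velocity, large uncertainty diagonal."""
    x, y = detection.centroid
    return TrackState(
        state=np.array([x, y, 0.0, 0.0]),
        covariance=np.diag([100.0, 100.0, 1e4, 1e4]),
        frames_since_detection=0,
        initialized=True,
    )


def _check_spd(P: np.ndarray) -> None:
    if not np.allclose(P, P.T, atol=1e-8):
        raise np.linalg.LinAlgError("covariance not symmetric")
    np.linalg.cholesky((P + P.T) / 2)  # raises if not positive-definite


def kalman_step(
    state: TrackState,
    detection: Detection | None,
    q: float = 1.0,
    r: float = 2.0,
) -> TrackState:
    """One predict(+update) cycle of the constant-velocity filter.

    With a valid detection the standard measurement update on (x, y) is
    applied (Joseph-form covariance for numerical symmetry); otherwise the
    prediction stands and ``frames_since_detection`` increments.
    """
    _check_spd(state.covariance)
    Q = q * np.eye(4)
    x = _F @ state.state
    P = _F @ state.covariance @ _F.T + Q
    if detection is None or not detection.valid:
        return TrackState(
            state=x,
            covariance=(P + P.T) / 2,
            frames_since_detection=state.frames_since_detection + 1,
            initialized=state.initialized,
        )
    z = np.array(detection.centroid)
    R = r * np.eye(2)
    S = _H @ P @ _H.T + R
    K = P @ _H.T @ np.linalg.inv(S)
    x = x + K @ (z - _H @ x)
    IKH = np.eye(4) - K @ _H
    P = IKH @ P @ IKH.T + K @ R @ K.T
    return TrackState(
        state=x,
        covariance=(P + P.T) / 2,
        frames_since_detection=0,
        initialized=True,
    )


def track_sequence(
    frames: Sequence[np.ndarray],
    hsv: HSVRange | None = None,
    q: float = 1.0,
    r: float = 2.0,
    max_misses: int = 15,
) -> list[TrackState]:
    """Segment and track the marker through a frame sequence.

    Returns one TrackState per frame. States before the first detection (and
    after a track is lost) are flagged ``initialized=False``; a track is lost
    after ``max_misses`` consecutive missed detections and re-initialised on
    the next detection.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    hsv = hsv or HSVRange()
    states: list[TrackState] = []
    current: TrackState | None = None
    for frame in frames:
        det = segment_marker(frame, hsv)
        if current is None or not current.initialized:
            if det.valid:
                current = init_track(det)
            else:
                current = TrackState(initialized=False)
        else:
            current = kalman_step(current, det, q=q, r=r)
            if current.frames_since_detection > max_misses:
                current = replace(current, initialized=False)
        states.append(current)
    return states
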