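"""Facial-mesh data model and per-frame eye/mouth aspect ratios.

A 468-point facial mesh (the index convention used by Attention-Mesh-style
extractors) carries a fixed set of keypoints around the eye and mouth
contours.  The eye aspect ratio (EAR) is the mean of three eyelid vertical
separations divided by the eye-corner width; it rests at an open baseline
and collapses toward zero when the eye closes.  The mouth aspect ratio
(MAR) is the analogous statistic over eight outer-lip keypoints and rises
sharply during a yawn.

Only x and y enter the ratios: the formulas are strictly planar, so a z
coordinate, when present, is carried through but ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "LandmarkFrame",
    "KeypointMap",
    "RatioSample",
    "MissingLandmarkError",
    "N_MESH_POINTS",
    "compute_ear",
    "compute_mar",
    "compute_ratio_series",
]

#: Number of points in a full facial mesh.
N_MESH_POINTS = 468

# Right eye: corners 362/263, eyelid pairs (384,381) (386,374) (388,390).
# Left eye:  corners 33/133, eyelid pairs (161,163) (159,145) (157,154).
# Mouth: corners 61/291, lip pairs (39,181) (0,17) (269,405).
_RIGHT_EYE_WIDTH = (362, 263)
_RIGHT_EYE_VERTICAL = ((384, 381), (386, 374), (388, 390))
_LEFT_EYE_WIDTH = (33, 133)
_LEFT_EYE_VERTICAL = ((161, 163), (159, 145), (157, 154))
_MOUTH_WIDTH = (61, 291)
_MOUTH_VERTICAL = ((39, 181), (0, 17), (269, 405))

#: All landmark indices a frame must provide for ratio computation.
REQUIRED_INDICES = frozenset(
    {i for pair in (_RIGHT_EYE_WIDTH, _LEFT_EYE_WIDTH, _MOUTH_WIDTH) for i in pair}
    | {i for group in (_RIGHT_EYE_VERTICAL, _LEFT_EYE_VERTICAL, _MOUTH_VERTICAL)
       for pair in group for i in pair}
)


class MissingLandmarkError(ValueError):
    """A frame lacks (or has non-finite values at) a required landmark index."""

    def __init__(self, frame_index: int, landmark_index: int):
        self.frame_index = frame_index
        self.landmark_index = landmark_index
        super().__init__(
            f"frame {frame_index}: required landmark index {landmark_index} "
            f"is missing or non-finite"
        )


@dataclass(frozen=True)
class KeypointMap:
    """Which mesh indices feed each term of the aspect-ratio formulas.

    Defaults follow the standard 468-point mesh numbering; pass alternative
    pairs to adapt to a different landmark convention.  "Left" and "right"
    name the index groups of the reference convention (362/263 vs 33/133);
    some extractors mirror these, which leaves the averaged EAR unchanged.
    """

    right_eye_width: tuple[int, int] = _RIGHT_EYE_WIDTH
    right_eye_vertical: tuple[tuple[int, int], ...] = _RIGHT_EYE_VERTICAL
    left_eye_width: tuple[int, int] = _LEFT_EYE_WIDTH
    left_eye_vertical: tuple[tuple[int, int], ...] = _LEFT_EYE_VERTICAL
    mouth_width: tuple[int, int] = _MOUTH_WIDTH
    mouth_vertical: tuple[tuple[int, int], ...] = _MOUTH_VERTICAL

    def __post_init__(self):
        for name, width, vertical in (
            ("right_eye", self.right_eye_width, self.right_eye_vertical),
            ("left_eye", self.left_eye_width, self.left_eye_vertical),
            ("mouth", self.mouth_width, self.mouth_vertical),
        ):
            flat = list(width) + [i for pair in vertical for i in pair]
            if len(set(flat)) != len(flat):
                raise ValueError(f"{name}: keypoint indices must be distinct")

    def all_indices(self) -> frozenset[int]:
        flat: set[int] = set()
        for width, vertical in (
            (self.right_eye_width, self.right_eye_vertical),
            (self.left_eye_width, self.left_eye_vertical),
            (self.mouth_width, self.mouth_vertical),
        ):
            flat.update(width)
            flat.update(i for pair in vertical for i in pair)
        return frozenset(flat)


@dataclass
class LandmarkFrame:
    """One video frame's indexed facial mesh.

    ``points`` is an (n, 2) or (n, 3) float array indexed by landmark
    number (0-based).  x and y must share one length unit — pixel
    coordinates are the recommended choice, since per-axis normalized
    coordinates distort the ratios on non-square images.
    """

    frame_index: int
    points: np.ndarray
    timestamp: Optional[float] = None  # seconds

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise ValueError("points must be an (n, 2) or (n, 3) array")
        self.points = pts

    def has_index(self, idx: int) -> bool:
        return (
            0 <= idx < len(self.points)
            and bool(np.all(np.isfinite(self.points[idx, :2])))
        )

    def require(self, idx: int) -> np.ndarray:
        """Return point ``idx`` or raise :class:`MissingLandmarkError`."""
        if not self.has_index(idx):
            raise MissingLandmarkError(self.frame_index, idx)
        return self.points[idx]


@dataclass(frozen=True)
class RatioSample:
    """Per-frame aspect ratios.

    ``valid`` is False when the frame was geometrically degenerate
    (zero eye or mouth width); the ratios are then NaN and downstream
    state logic treats the frame as neither closed-eye nor yawning.
    """

    frame_index: int
    ear_left: float
    ear_right: float
    ear: float
    mar: float
    valid: bool = True


def _gap_sum(frame: LandmarkFrame, pairs: Iterable[tuple[int, int]]) -> float:
    return sum(abs(frame.require(a)[1] - frame.require(b)[1]) for a, b in pairs)


def _width(frame: LandmarkFrame, pair: tuple[int, int]) -> float:
    a, b = pair
    return abs(frame.require(a)[0] - frame.require(b)[0])


def compute_ear(
    frame: LandmarkFrame, keypoints: KeypointMap | None = None
) -> tuple[float, float, float]:
    """Eye aspect ratios ``(ear_left, ear_right, ear)`` for one frame.

    Each per-eye ratio is the sum of the three eyelid vertical |Δy|
    separations over three times the eye-corner |Δx| width; ``ear`` is
    the mean of the two eyes.  z coordinates are ignored.

    Raises
    ------
    MissingLandmarkError
        if a required index is absent or non-finite.
    ZeroDivisionError
        if either eye has zero corner width (degenerate geometry);
        callers building a series should catch this and flag the frame
        invalid rather than abort.
    """
    kp = keypoints or KeypointMap()
    w_right = _width(frame, kp.right_eye_width)
    w_left = _width(frame, kp.left_eye_width)
    if w_right == 0.0 or w_left == 0.0:
        raise ZeroDivisionError(
            f"frame {frame.frame_index}: zero eye-corner width"
        )
    ear_right = _gap_sum(frame, kp.right_eye_vertical) / (3.0 * w_right)
    ear_left = _gap_sum(frame, kp.left_eye_vertical) / (3.0 * w_left)
    return ear_left, ear_right, (ear_left + ear_right) / 2.0


def compute_mar(frame: LandmarkFrame, keypoints: KeypointMap | None = None) -> float:
    """Mouth aspect ratio: three outer-lip |Δy| gaps over 3× mouth width.

    Raises :class:`MissingLandmarkError` for absent indices and
    ``ZeroDivisionError`` for zero mouth-corner width.
    """
    kp = keypoints or KeypointMap()
    w = _width(frame, kp.mouth_width)
    if w == 0.0:
        raise ZeroDivisionError(f"frame {frame.frame_index}: zero mouth width")
    return _gap_sum(frame, kp.mouth_vertical) / (3.0 * w)


def compute_ratio_series(
    frames: Sequence[LandmarkFrame], keypoints: KeypointMap | None = None
) -> list[RatioSample]:
    """One :class:`RatioSample` per frame, in order.

    Frames must be sorted by strictly increasing ``frame_index``.
    Degenerate frames (zero eye or mouth width) yield ``valid=False``
    samples with NaN ratios instead of aborting the run; a missing
    landmark index is a hard error, since it indicates a malformed
    input rather than a transient geometric collapse.
    """
    kp = keypoints or KeypointMap()
    last = -1
    out: list[RatioSample] = []
    for frame in frames:
        if frame.frame_index <= last:
            raise ValueError(
                f"frame indices must be strictly increasing: "
                f"{frame.frame_index} after {last}"
            )
        last = frame.frame_index
        try:
            ear_left, ear_right, ear = compute_ear(frame, kp)
            mar = compute_mar(frame, kp)
        except ZeroDivisionError:
            out.append(
                RatioSample(frame.frame_index, math.nan, math.nan,
                            math.nan, math.nan, valid=False)
            )
            continue
        out.append(RatioSample(frame.frame_index, ear_left, ear_right, ear, mar))
    return out
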