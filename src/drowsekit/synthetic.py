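"""Synthetic facial-kinematics generator with ground truth.

Produces 468-point landmark-frame sequences in which blinks, sustained
eye closures and yawns are scripted events with known boundaries, so the
whole ratio → episode → verdict pipeline can be exercised and verified
without any video data.

The neutral template rests at an open-eye EAR baseline of 0.10 and a
closed-mouth MAR of 0.25 (inside the 0.2–0.3 band typical of a resting
mouth).  During an eye event the eyelid keypoints collapse until the EAR
plateaus near 0.005; during a yawn the lip keypoints spread until the
MAR plateaus near 1.1.  Transitions are linear ramps.  The ramp frames
outside an event approach — but never cross — the default per-frame
decision thresholds (EAR 0.02, MAR 0.65), so the frames that are truly
in-state are exactly the scripted event frames and detected episode
boundaries can be compared to the script frame-for-frame.

Face geometry uses a 640-unit face width, so noise magnitudes read as
pixel-like units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .episodes import FrameState, Thresholds
from .landmarks import KeypointMap, LandmarkFrame, N_MESH_POINTS

__all__ = [
    "EventSpec",
    "SimulationConfig",
    "SimulationTruth",
    "neutral_mesh",
    "simulate",
    "default_yawn",
]

_EYE_KINDS = ("blink", "closure")
_MOUTH_KINDS = ("yawn",)

# Template geometry (length units ~ pixels; face spans x = 0..640).
_EYE_WIDTH = 90.0
_MOUTH_WIDTH = 120.0
_LEFT_EYE_X = (140.0, 230.0)    # corners 33, 133
_RIGHT_EYE_X = (410.0, 500.0)   # corners 362, 263
_MOUTH_X = (260.0, 380.0)       # corners 61, 291
_EYE_CY = 300.0
_MOUTH_CY = 520.0
_LEFT_EYE_COLS = (155.0, 185.0, 215.0)   # x of the three eyelid pairs
_RIGHT_EYE_COLS = (425.0, 455.0, 485.0)
_MOUTH_COLS = (290.0, 320.0, 350.0)


@dataclass(frozen=True)
class EventSpec:
    """One scripted facial event.

    ``kind``: "blink" or "closure" (eye channel) or "yawn" (mouth).
    ``onset``: first frame of the event (inclusive).
    ``duration``: frames spent at the event plateau.
    ``intensity``: 1 drives the ratio all the way to the configured
    plateau; smaller values stop part-way (a weak event may then never
    cross the decision threshold, which the ground truth reflects).
    """

    kind: str
    onset: int
    duration: int
    intensity: float = 1.0

    def __post_init__(self):
        if self.kind not in _EYE_KINDS + _MOUTH_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration < 1:
            raise ValueError("duration must be >= 1")
        if not (0.0 < self.intensity <= 1.0):
            raise ValueError("intensity must lie in (0, 1]")

    @property
    def end(self) -> int:
        return self.onset + self.duration


@dataclass(frozen=True)
class SimulationConfig:
    """Sequence length, event script, kinematic plateaus and noise.

    ``fps`` matters only for converting durations in seconds to frames
    (see :func:`default_yawn`); the simulation itself is frame-indexed.
    ``ramp`` is the length in frames of the linear attack and release
    flanking each event.  ``noise_sd`` is the standard deviation of the
    isotropic Gaussian perturbation added per coordinate after
    animation, in the template's pixel-like units.
    """

    n_frames: int
    fps: float = 23.0
    events: tuple[EventSpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    baseline_ear: float = 0.10
    closed_ear: float = 0.005
    baseline_mar: float = 0.25
    yawn_mar: float = 1.1
    ramp: int = 10

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.2 <= self.baseline_mar <= 0.3):
            raise ValueError("baseline_mar must lie in the resting band [0.2, 0.3]")
        if not (self.closed_ear < 0.02 < self.baseline_ear):
            raise ValueError("need closed_ear < 0.02 < baseline_ear")
        if self.yawn_mar <= 0.65:
            raise ValueError("yawn_mar must exceed the yawn threshold 0.65")
        if self.ramp < 0:
            raise ValueError("ramp must be >= 0")
        for ev in self.events:
            if ev.end > self.n_frames:
                raise ValueError(
                    f"event {ev.kind}@{ev.onset} extends past n_frames"
                )
        for channel in (_EYE_KINDS, _MOUTH_KINDS):
            evs = sorted(
                (e for e in self.events if e.kind in channel),
                key=lambda e: e.onset,
            )
            for a, b in zip(evs, evs[1:]):
                if b.onset < a.end:
                    raise ValueError(
                        f"overlapping {'/'.join(channel)} events at "
                        f"frames {b.onset} < {a.end}"
                    )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth: per-frame states plus the event script."""

    states: tuple[FrameState, ...]
    events: tuple[EventSpec, ...]


def _template(config: SimulationConfig) -> np.ndarray:
    """Neutral 468-point mesh with EAR/MAR at the configured baselines."""
    kp = KeypointMap()
    pts = np.zeros((N_MESH_POINTS, 3))
    # Non-keypoint filler: static ring around the face oval.
    idx = np.arange(N_MESH_POINTS)
    ang = 2.0 * np.pi * idx / N_MESH_POINTS
    pts[:, 0] = 320.0 + 300.0 * np.cos(ang)
    pts[:, 1] = 400.0 + 380.0 * np.sin(ang)
    pts[kp.left_eye_width[0], :2] = (_LEFT_EYE_X[0], _EYE_CY)
    pts[kp.left_eye_width[1], :2] = (_LEFT_EYE_X[1], _EYE_CY)
    pts[kp.right_eye_width[0], :2] = (_RIGHT_EYE_X[0], _EYE_CY)
    pts[kp.right_eye_width[1], :2] = (_RIGHT_EYE_X[1], _EYE_CY)
    pts[kp.mouth_width[0], :2] = (_MOUTH_X[0], _MOUTH_CY)
    pts[kp.mouth_width[1], :2] = (_MOUTH_X[1], _MOUTH_CY)
    _set_eyelids(pts, kp, config.baseline_ear)
    _set_lips(pts, kp, config.baseline_mar)
    return pts


def _set_eyelids(pts: np.ndarray, kp: KeypointMap, ear: float) -> None:
    # Each of the three pairs carries gap = ear * width, so the summed
    # gaps over 3*width reproduce `ear` exactly.
    gap = ear * _EYE_WIDTH
    for pairs, cols in (
        (kp.left_eye_vertical, _LEFT_EYE_COLS),
        (kp.right_eye_vertical, _RIGHT_EYE_COLS),
    ):
        for (top, bottom), x in zip(pairs, cols):
            pts[top, :2] = (x, _EYE_CY - gap / 2.0)
            pts[bottom, :2] = (x, _EYE_CY + gap / 2.0)


def _set_lips(pts: np.ndarray, kp: KeypointMap, mar: float) -> None:
    gap = mar * _MOUTH_WIDTH
    for (top, bottom), x in zip(kp.mouth_vertical, _MOUTH_COLS):
        pts[top, :2] = (x, _MOUTH_CY - gap / 2.0)
        pts[bottom, :2] = (x, _MOUTH_CY + gap / 2.0)


def neutral_mesh(config: SimulationConfig | None = None) -> LandmarkFrame:
    """A single neutral frame whose EAR/MAR equal the configured baselines."""
    cfg = config or SimulationConfig(n_frames=1)
    return LandmarkFrame(frame_index=0, points=_template(cfg))


def default_yawn(config: SimulationConfig, onset: int = 0) -> EventSpec:
    """A yawn of typical physiological length: about 6.5 s at ``fps``."""
    duration = round(6.5 * config.fps)
    return EventSpec(kind="yawn", onset=onset, duration=duration)


def _ratio_track(
    n: int,
    events: Sequence[EventSpec],
    baseline: float,
    plateau_full: float,
    edge: float,
    ramp: int,
) -> np.ndarray:
    """Per-frame target ratio for one channel (eyes or mouth).

    Event frames sit at the plateau; the ``ramp`` frames before and
    after interpolate linearly between the baseline and the decision
    edge without ever reaching it, so out-of-event frames always stay
    on the open side of the threshold.
    """
    closing = plateau_full < baseline  # eyes close downward, mouths open upward
    track = np.full(n, baseline)

    def tighten(i: int, value: float) -> None:
        if 0 <= i < n:
            track[i] = min(track[i], value) if closing else max(track[i], value)

    for ev in events:
        plateau = baseline + (plateau_full - baseline) * ev.intensity
        for f in range(ev.onset, min(ev.end, n)):
            tighten(f, plateau)
        for k in range(1, ramp + 1):
            frac = k / (ramp + 1)
            val = baseline + (edge - baseline) * frac
            # A weak event's plateau may be shallower than the ramp edge;
            # never overshoot it.
            val = max(val, plateau) if closing else min(val, plateau)
            tighten(ev.onset - 1 - ramp + k, val)           # attack
            tighten(ev.end + ramp - k, val)                 # release
    return track


def simulate(
    config: SimulationConfig,
) -> tuple[list[LandmarkFrame], SimulationTruth]:
    """Render the scripted sequence and its ground truth.

    Returns one :class:`~drowsekit.landmarks.LandmarkFrame` per frame
    (noise applied after animation, seeded and reproducible) and a
    :class:`SimulationTruth` whose per-frame states mark a frame closed
    or yawning iff its *noiseless* EAR/MAR crosses the default
    thresholds.
    """
    kp = KeypointMap()
    thr = Thresholds()
    n = config.n_frames
    eye_events = [e for e in config.events if e.kind in _EYE_KINDS]
    mouth_events = [e for e in config.events if e.kind in _MOUTH_KINDS]
    ear_track = _ratio_track(
        n, eye_events, config.baseline_ear, config.closed_ear,
        thr.ear_closed, config.ramp,
    )
    mar_track = _ratio_track(
        n, mouth_events, config.baseline_mar, config.yawn_mar,
        thr.mar_yawn, config.ramp,
    )

    rng = np.random.default_rng(config.seed)
    base = _template(config)
    frames: list[LandmarkFrame] = []
    states: list[FrameState] = []
    for i in range(n):
        pts = base.copy()
        _set_eyelids(pts, kp, ear_track[i])
        _set_lips(pts, kp, mar_track[i])
        if config.noise_sd > 0:
            pts = pts + rng.normal(0.0, config.noise_sd, pts.shape)
        frames.append(
            LandmarkFrame(frame_index=i, points=pts, timestamp=i / config.fps)
        )
        states.append(
            FrameState(
                frame_index=i,
                eyes_closed=bool(ear_track[i] < thr.ear_closed),
                yawning=bool(mar_track[i] > thr.mar_yawn),
            )
        )
    return frames, SimulationTruth(tuple(states), config.events)
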