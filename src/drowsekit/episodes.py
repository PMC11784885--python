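"""Per-frame closed-eye / yawning states and run-length episode extraction.

A frame is *yawning* when its mouth aspect ratio strictly exceeds the yawn
threshold (0.65 by default), and *closed-eye* when its eye aspect ratio
falls strictly below the closure threshold (0.02 by default).  When an
auxiliary feature detector supplies per-frame class labels, the yawn test
additionally requires the open-mouth label (AND) while the eye test is
satisfied by either the closed-eyes label or the ratio test (OR).

Maximal runs of a state form half-open episodes [start, end); the episode
duration end - start equals the number of in-state frames, so a 20-frame
closure has duration 20.  The longest episode per window is the
consecutive-frame statistic (F_e for eyes, F_m for yawns) that the cycle
classifier thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .landmarks import RatioSample

__all__ = [
    "EpisodeKind",
    "FrameState",
    "Thresholds",
    "DetectorLabels",
    "Episode",
    "frame_state",
    "state_series",
    "find_episodes",
    "max_consecutive",
]


class EpisodeKind(str, Enum):
    EYE_CLOSURE = "eye_closure"
    YAWN = "yawn"


@dataclass(frozen=True)
class Thresholds:
    """Per-frame decision thresholds.

    ``ear_closed``: EAR strictly below this marks the eyes closed.
    ``mar_yawn``: MAR strictly above this marks a yawning mouth.
    """

    ear_closed: float = 0.02
    mar_yawn: float = 0.65

    def __post_init__(self):
        if self.ear_closed <= 0 or self.mar_yawn <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass(frozen=True)
class DetectorLabels:
    """Optional per-frame class flags from a face-feature detector."""

    o_mouth: bool = False
    c_eyes: bool = False


@dataclass(frozen=True)
class FrameState:
    frame_index: int
    eyes_closed: bool
    yawning: bool
    valid: bool = True


@dataclass(frozen=True)
class Episode:
    """A maximal run of one state, half-open: frames start .. end-1."""

    kind: EpisodeKind
    start: int
    end: int  # exclusive

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("episode end must exceed start")

    @property
    def duration(self) -> int:
        return self.end - self.start


def frame_state(
    sample: RatioSample,
    thresholds: Thresholds | None = None,
    detector_labels: Optional[DetectorLabels] = None,
) -> FrameState:
    """Classify one frame as closed-eye and/or yawning.

    Comparisons are strict: MAR exactly at the yawn threshold, or EAR
    exactly at the closure threshold, leaves the frame in the open state.
    Invalid samples are neither closed nor yawning.
    """
    thr = thresholds or Thresholds()
    if not sample.valid:
        return FrameState(sample.frame_index, False, False, valid=False)
    mar_high = sample.mar > thr.mar_yawn
    ear_low = sample.ear < thr.ear_closed
    if detector_labels is None:
        yawning = mar_high
        eyes_closed = ear_low
    else:
        yawning = detector_labels.o_mouth and mar_high
        eyes_closed = detector_labels.c_eyes or ear_low
    return FrameState(sample.frame_index, eyes_closed, yawning)


def state_series(
    samples: Sequence[RatioSample],
    thresholds: Thresholds | None = None,
    detector_labels: Optional[Sequence[DetectorLabels]] = None,
) -> list[FrameState]:
    """Apply :func:`frame_state` across a ratio series."""
    if detector_labels is not None and len(detector_labels) != len(samples):
        raise ValueError("detector_labels must align one-to-one with samples")
    thr = thresholds or Thresholds()
    return [
        frame_state(s, thr, detector_labels[i] if detector_labels else None)
        for i, s in enumerate(samples)
    ]


def find_episodes(
    states: Sequence[FrameState],
    kind: EpisodeKind,
    gap_tolerance: int = 0,
) -> list[Episode]:
    """Maximal runs of ``kind``'s flag as sorted, disjoint episodes.

    ``gap_tolerance`` g > 0 merges runs separated by at most g
    out-of-state frames into one episode spanning the gap; the merged
    duration counts the gap frames.  Merging is meant for the
    consecutive-frame statistics only — PERCLOS accounting should use
    the raw (g = 0) episodes so the gap frames do not inflate the score.

    States must be contiguous in ``frame_index``.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    for prev, cur in zip(states, states[1:]):
        if cur.frame_index != prev.frame_index + 1:
            raise ValueError(
                f"states must be contiguous: frame {cur.frame_index} "
                f"follows {prev.frame_index}"
            )
    flag = (
        (lambda s: s.eyes_closed)
        if kind == EpisodeKind.EYE_CLOSURE
        else (lambda s: s.yawning)
    )
    raw: list[Episode] = []
    start: Optional[int] = None
    for s in states:
        if flag(s):
            if start is None:
                start = s.frame_index
        elif start is not None:
            raw.append(Episode(kind, start, s.frame_index))
            start = None
    if start is not None:
        raw.append(Episode(kind, start, states[-1].frame_index + 1))
    if gap_tolerance == 0 or not raw:
        return raw
    merged = [raw[0]]
    for ep in raw[1:]:
        if ep.start - merged[-1].end <= gap_tolerance:
            merged[-1] = Episode(kind, merged[-1].start, ep.end)
        else:
            merged.append(ep)
    return merged


def max_consecutive(episodes: Sequence[Episode]) -> int:
    """Longest episode duration in frames (0 if none)."""
    return max((ep.duration for ep in episodes), default=0)
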