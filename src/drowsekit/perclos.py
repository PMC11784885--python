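"""PERCLOS cycle scoring and the normal/fatigued verdict.

The frame stream is tiled into unit cycles of F0 frames (150 by default,
about 6.5 s at ~23 fps).  Within each cycle the eye PERCLOS score
P_eyes is the summed duration of closed-eye episodes, clipped to the
cycle, divided by F0; P_mouth is the yawning analogue.  F_e and F_m are
the longest consecutive closed-eye and yawning runs touching the cycle.
A cycle is *fatigued* when any enabled criterion holds (inclusive
comparisons):

    P_eyes >= 0.15   or   P_mouth >= 0.15   or   F_e >= 20   or   F_m >= 30

and *normal* otherwise.  The overall verdict for a sequence is fatigued
iff any complete cycle is fatigued.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

from .episodes import (
    Episode,
    EpisodeKind,
    Thresholds,
    find_episodes,
    max_consecutive,
    state_series,
)
from .landmarks import KeypointMap, LandmarkFrame, RatioSample, compute_ratio_series

__all__ = [
    "Criterion",
    "CycleConfig",
    "CycleSummary",
    "Verdict",
    "perclos_score",
    "classify_summary",
    "classify_sequence",
    "ALL_CRITERIA",
]

#: Criterion identifiers used in ``CycleConfig.criteria_enabled``.
PERCLOS_EYES = "perclos_eyes"
PERCLOS_MOUTH = "perclos_mouth"
FE = "fe"
FM = "fm"
ALL_CRITERIA = frozenset({PERCLOS_EYES, PERCLOS_MOUTH, FE, FM})

Criterion = str
Verdict = str  # "normal" | "fatigued"


@dataclass(frozen=True)
class CycleConfig:
    """Unit-cycle length, decision thresholds and tiling stride.

    ``f0``
        cycle length in frames (default 150).
    ``perclos_threshold``
        PERCLOS score at or above which a cycle is fatigued (default 0.15,
        applied to both the eye and the mouth score).
    ``fe_threshold`` / ``fm_threshold``
        consecutive closed-eye / yawning frame counts at or above which a
        cycle is fatigued (defaults 20 and 30).
    ``stride``
        window step in frames; defaults to ``f0`` (non-overlapping unit
        cycles).  A smaller stride gives sliding-window evaluation for
        streaming use.
    ``criteria_enabled``
        subset of {perclos_eyes, perclos_mouth, fe, fm}; disabling
        criteria isolates a single decision boundary.
    """

    f0: int = 150
    perclos_threshold: float = 0.15
    fe_threshold: int = 20
    fm_threshold: int = 30
    stride: int | None = None
    criteria_enabled: frozenset[Criterion] = ALL_CRITERIA

    def __post_init__(self):
        if self.f0 < 1:
            raise ValueError("f0 must be >= 1")
        if not (0.0 < self.perclos_threshold < 1.0):
            raise ValueError("perclos_threshold must lie in (0, 1)")
        if self.fe_threshold <= 0 or self.fm_threshold <= 0:
            raise ValueError("frame-count thresholds must be positive")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1")
        unknown = set(self.criteria_enabled) - ALL_CRITERIA
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        object.__setattr__(
            self, "criteria_enabled", frozenset(self.criteria_enabled)
        )

    @property
    def effective_stride(self) -> int:
        return self.stride if self.stride is not None else self.f0


@dataclass(frozen=True)
class CycleSummary:
    """Scores and verdict for one unit cycle [f_start, f_end)."""

    f_start: int
    f_end: int
    p_eyes: float
    p_mouth: float
    fe: int
    fm: int
    verdict: Verdict
    triggered: frozenset[Criterion]
    partial: bool = False


def perclos_score(
    episodes: Sequence[Episode], window: tuple[int, int], f0: int
) -> float:
    """Fraction of a window covered by episodes: Σ clipped durations / f0.

    ``window`` is half-open [f_start, f_end).  Episodes contribute only
    their overlap with the window, so the score lies in [0, 1] whenever
    the window length is f0.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    f_start, f_end = window
    total = 0
    for ep in episodes:
        total += max(0, min(ep.end, f_end) - max(ep.start, f_start))
    return total / f0


def classify_summary(
    p_eyes: float,
    p_mouth: float,
    fe: int,
    fm: int,
    config: CycleConfig | None = None,
) -> tuple[Verdict, frozenset[Criterion]]:
    """Apply the fatigue rule to one cycle's scores.

    Returns the verdict and the set of criteria that fired.  All
    comparisons are inclusive (>=); the verdict is fatigued iff the
    triggered set is non-empty.
    """
    cfg = config or CycleConfig()
    triggered = set()
    if PERCLOS_EYES in cfg.criteria_enabled and p_eyes >= cfg.perclos_threshold:
        triggered.add(PERCLOS_EYES)
    if PERCLOS_MOUTH in cfg.criteria_enabled and p_mouth >= cfg.perclos_threshold:
        triggered.add(PERCLOS_MOUTH)
    if FE in cfg.criteria_enabled and fe >= cfg.fe_threshold:
        triggered.add(FE)
    if FM in cfg.criteria_enabled and fm >= cfg.fm_threshold:
        triggered.add(FM)
    verdict = "fatigued" if triggered else "normal"
    return verdict, frozenset(triggered)


def _overlapping_max(episodes: Sequence[Episode], f_start: int, f_end: int) -> int:
    # Consecutive-frame statistics use the full duration of any episode
    # touching the window: continuity is a property of the behaviour, not
    # of the tiling.
    return max(
        (ep.duration for ep in episodes if ep.start < f_end and ep.end > f_start),
        default=0,
    )


def classify_sequence(
    data: Union[Sequence[LandmarkFrame], Sequence[RatioSample]],
    thresholds: Thresholds | None = None,
    config: CycleConfig | None = None,
    keypoints: KeypointMap | None = None,
) -> tuple[list[CycleSummary], Verdict]:
    """Full pipeline: ratios → states → episodes → per-cycle verdicts.

    ``data`` may be landmark frames (ratios are computed first) or an
    already-computed ratio series.  The sequence is tiled into windows
    of ``f0`` frames at the configured stride; a trailing partial window
    is evaluated with f0 as the divisor and flagged ``partial``.  The
    overall verdict is fatigued iff any complete cycle is fatigued.
    """
    if len(data) == 0:
        raise ValueError("input sequence is empty")
    cfg = config or CycleConfig()
    if isinstance(data[0], LandmarkFrame):
        samples = compute_ratio_series(data, keypoints)  # type: ignore[arg-type]
    else:
        samples = list(data)  # type: ignore[assignment]
    states = state_series(samples, thresholds)
    eye_eps = find_episodes(states, EpisodeKind.EYE_CLOSURE)
    yawn_eps = find_episodes(states, EpisodeKind.YAWN)

    first = states[0].frame_index
    last = states[-1].frame_index + 1
    summaries: list[CycleSummary] = []
    overall = "normal"
    f_start = first
    while f_start < last:
        f_end = f_start + cfg.f0
        partial = f_end > last
        window = (f_start, min(f_end, last))
        p_eyes = perclos_score(eye_eps, window, cfg.f0)
        p_mouth = perclos_score(yawn_eps, window, cfg.f0)
        fe = _overlapping_max(eye_eps, *window)
        fm = _overlapping_max(yawn_eps, *window)
        verdict, triggered = classify_summary(p_eyes, p_mouth, fe, fm, cfg)
        summaries.append(
            CycleSummary(f_start, f_end, p_eyes, p_mouth, fe, fm,
                         verdict, triggered, partial=partial)
        )
        if verdict == "fatigued" and not partial:
            overall = "fatigued"
        f_start += cfg.effective_stride
    return summaries, overall
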