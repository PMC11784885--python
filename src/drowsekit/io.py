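"""Readers, writers and run configuration.

Two landmark interchange formats are supported, both plain delimited
text with a header:

* long table — one row per landmark: ``frame,index,x,y[,z]``;
* wide stream — one row per frame: ``frame`` followed by
  ``x0,y0[,z0],x1,y1[,z1],…`` for all 468 points in index order.

Landmark indices are 0-based throughout.  Coordinates are pixels by
default; extractors that emit per-axis normalized coordinates can be
read with ``coordinate_mode="normalized"`` plus the image dimensions,
which rescales x by the width and y by the height so the aspect ratios
are computed in isotropic units.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .episodes import Episode, FrameState, Thresholds
from .landmarks import (
    REQUIRED_INDICES,
    LandmarkFrame,
    MissingLandmarkError,
    RatioSample,
)
from .perclos import CycleConfig, CycleSummary, Verdict
from .boxeval import Box, Detection
from .synthetic import EventSpec, SimulationTruth

__all__ = [
    "RunConfig",
    "VerdictReport",
    "read_landmark_table",
    "write_landmark_table",
    "write_ratio_series",
    "read_ratio_series",
    "write_states",
    "write_episodes",
    "write_truth",
    "read_truth",
    "read_ground_truth_boxes",
    "read_detections",
    "write_report",
]

CoordinateMode = Literal["pixel", "normalized"]


@dataclass
class RunConfig:
    """Everything a detection run needs, loadable from a YAML mapping."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    cycle: CycleConfig = field(default_factory=CycleConfig)
    coordinate_mode: CoordinateMode = "pixel"
    image_size: Optional[tuple[int, int]] = None  # (width, height)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.get("thresholds", {}))
        cyc_raw = dict(raw.get("cycle", {}))
        if "criteria_enabled" in cyc_raw:
            cyc_raw["criteria_enabled"] = frozenset(cyc_raw["criteria_enabled"])
        cyc = CycleConfig(**cyc_raw)
        size = raw.get("image_size")
        return cls(
            thresholds=thr,
            cycle=cyc,
            coordinate_mode=raw.get("coordinate_mode", "pixel"),
            image_size=tuple(size) if size else None,
        )

    def provenance(self) -> dict:
        return {
            "thresholds": asdict(self.thresholds),
            "cycle": {
                "f0": self.cycle.f0,
                "perclos_threshold": self.cycle.perclos_threshold,
                "fe_threshold": self.cycle.fe_threshold,
                "fm_threshold": self.cycle.fm_threshold,
                "stride": self.cycle.effective_stride,
                "criteria_enabled": sorted(self.cycle.criteria_enabled),
            },
            "coordinate_mode": self.coordinate_mode,
            "image_size": self.image_size,
        }


def _validate_frame_indices(frame_index: int, present: set[int]) -> None:
    missing = REQUIRED_INDICES - present
    if missing:
        raise MissingLandmarkError(frame_index, min(missing))


def read_landmark_table(
    path: str | Path,
    coordinate_mode: CoordinateMode = "pixel",
    image_size: Optional[tuple[int, int]] = None,
) -> list[LandmarkFrame]:
    """Read landmark frames from either declared text format.

    The format is inferred from the header.  Every frame is checked for
    the full set of indices the ratio formulas require; a violation
    raises :class:`~drowsekit.landmarks.MissingLandmarkError` naming the
    frame and index.
    """
    path = Path(path)
    if coordinate_mode == "normalized" and image_size is None:
        raise ValueError("normalized coordinates require image_size=(width, height)")
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: malformed delimited file: {exc}") from exc
    cols = list(df.columns)
    if cols[:4] == ["frame", "index", "x", "y"]:
        frames = _frames_from_long(df, path)
    elif cols and cols[0] == "frame" and cols[1].startswith("x"):
        frames = _frames_from_wide(df)
    else:
        raise ValueError(
            f"{path}: unrecognized header {cols[:5]}; expected the long "
            f"(frame,index,x,y[,z]) or wide (frame,x0,y0,...) layout"
        )
    if coordinate_mode == "normalized":
        w, h = image_size
        for f in frames:
            f.points[:, 0] *= w
            f.points[:, 1] *= h
    for f in frames:
        finite = np.isfinite(f.points[:, :2]).all(axis=1)
        _validate_frame_indices(f.frame_index, set(np.nonzero(finite)[0]))
    return frames


def _frames_from_long(df: pd.DataFrame, path: Path) -> list[LandmarkFrame]:
    has_z = "z" in df.columns
    value_cols = ["frame", "index", "x", "y"] + (["z"] if has_z else [])
    numeric = df[value_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric[["frame", "index", "x", "y"]].isna().any(axis=1)
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"{path}: malformed row at line {row + 2} (1-based, incl. header)"
        )
    frames: list[LandmarkFrame] = []
    for frame_idx, group in numeric.groupby("frame", sort=True):
        n = int(group["index"].max()) + 1
        pts = np.full((n, 3 if has_z else 2), np.nan)
        idx = group["index"].to_numpy(dtype=int)
        pts[idx, 0] = group["x"].to_numpy()
        pts[idx, 1] = group["y"].to_numpy()
        if has_z:
            pts[idx, 2] = group["z"].fillna(0.0).to_numpy()
        frames.append(LandmarkFrame(frame_index=int(frame_idx), points=pts))
    return frames


def _frames_from_wide(df: pd.DataFrame) -> list[LandmarkFrame]:
    coord_cols = [c for c in df.columns if c != "frame"]
    has_z = any(c.startswith("z") for c in coord_cols)
    per_point = 3 if has_z else 2
    n_points = len(coord_cols) // per_point
    frames: list[LandmarkFrame] = []
    for _, row in df.iterrows():
        vals = row[coord_cols].to_numpy(dtype=float)
        pts = vals.reshape(n_points, per_point)
        frames.append(LandmarkFrame(frame_index=int(row["frame"]), points=pts))
    return frames


def write_landmark_table(
    frames: Sequence[LandmarkFrame],
    path: str | Path,
    layout: Literal["long", "wide"] = "long",
) -> None:
    """Write frames in the long (default) or wide text layout."""
    path = Path(path)
    if layout == "long":
        has_z = frames[0].points.shape[1] == 3
        records = []
        for f in frames:
            for i, p in enumerate(f.points):
                rec = {"frame": f.frame_index, "index": i, "x": p[0], "y": p[1]}
                if has_z:
                    rec["z"] = p[2]
                records.append(rec)
        pd.DataFrame.from_records(records).to_csv(path, index=False)
    elif layout == "wide":
        has_z = frames[0].points.shape[1] == 3
        axes = "xyz" if has_z else "xy"
        n = len(frames[0].points)
        cols = [f"{a}{i}" for i in range(n) for a in axes]
        data = np.stack([f.points.reshape(-1) for f in frames])
        df = pd.DataFrame(data, columns=cols)
        df.insert(0, "frame", [f.frame_index for f in frames])
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def write_ratio_series(samples: Sequence[RatioSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "frame": s.frame_index,
                "ear_left": s.ear_left,
                "ear_right": s.ear_right,
                "ear": s.ear,
                "mar": s.mar,
                "valid": s.valid,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def read_ratio_series(path: str | Path) -> list[RatioSample]:
    df = pd.read_csv(path)
    return [
        RatioSample(
            int(r.frame), float(r.ear_left), float(r.ear_right),
            float(r.ear), float(r.mar), bool(r.valid),
        )
        for r in df.itertuples()
    ]


def write_states(states: Sequence[FrameState], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "frame": s.frame_index,
                "eyes_closed": s.eyes_closed,
                "yawning": s.yawning,
                "valid": s.valid,
            }
            for s in states
        ]
    ).to_csv(path, index=False)


def write_episodes(episodes: Sequence[Episode], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"kind": e.kind.value, "start": e.start, "end": e.end,
             "duration": e.duration}
            for e in episodes
        ],
        columns=["kind", "start", "end", "duration"],
    ).to_csv(path, index=False)


def write_truth(truth: SimulationTruth, path: str | Path,
                events_path: Optional[str | Path] = None) -> None:
    """Sidecar ground truth: per-frame states plus (optionally) the script."""
    pd.DataFrame(
        [
            {"frame": s.frame_index, "eyes_closed": s.eyes_closed,
             "yawning": s.yawning}
            for s in truth.states
        ]
    ).to_csv(path, index=False)
    if events_path is not None:
        pd.DataFrame(
            [
                {"kind": e.kind, "onset": e.onset, "duration": e.duration,
                 "intensity": e.intensity}
                for e in truth.events
            ],
            columns=["kind", "onset", "duration", "intensity"],
        ).to_csv(events_path, index=False)


def read_truth(path: str | Path) -> list[FrameState]:
    df = pd.read_csv(path)
    return [
        FrameState(int(r.frame), bool(r.eyes_closed), bool(r.yawning))
        for r in df.itertuples()
    ]


def read_ground_truth_boxes(path: str | Path) -> list[tuple[str, Box]]:
    """Rows: class,x_min,y_min,x_max,y_max."""
    df = pd.read_csv(path)
    return [
        (str(r.loc["class"]),
         Box(float(r.x_min), float(r.y_min), float(r.x_max), float(r.y_max)))
        for _, r in df.iterrows()
    ]


def read_detections(path: str | Path) -> list[Detection]:
    """Rows: class,x_min,y_min,x_max,y_max,confidence."""
    df = pd.read_csv(path)
    return [
        Detection(
            str(r.loc["class"]),
            Box(float(r.x_min), float(r.y_min), float(r.x_max), float(r.y_max)),
            float(r.confidence),
        )
        for _, r in df.iterrows()
    ]


@dataclass
class VerdictReport:
    """Per-cycle rows, overall verdict and an auditable provenance block."""

    cycles: list[CycleSummary]
    overall: Verdict
    provenance: dict

    @classmethod
    def build(
        cls,
        cycles: Sequence[CycleSummary],
        overall: Verdict,
        config: RunConfig,
        input_path: Optional[str | Path] = None,
        seed: Optional[int] = None,
    ) -> "VerdictReport":
        from . import __version__

        prov = {"config": config.provenance(), "package_version": __version__}
        if input_path is not None:
            digest = hashlib.sha256(Path(input_path).read_bytes()).hexdigest()
            prov["input"] = {"path": str(input_path), "sha256": digest}
        if seed is not None:
            prov["seed"] = seed
        return cls(list(cycles), overall, prov)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "f_start": c.f_start,
                    "f_end": c.f_end,
                    "p_eyes": c.p_eyes,
                    "p_mouth": c.p_mouth,
                    "fe": c.fe,
                    "fm": c.fm,
                    "triggered": "|".join(sorted(c.triggered)),
                    "verdict": c.verdict,
                    "partial": c.partial,
                }
                for c in self.cycles
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "overall": self.overall,
                "cycles": self.to_frame().to_dict(orient="records"),
                "provenance": self.provenance,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [self.to_frame().to_string(index=False),
                 f"overall verdict: {self.overall}",
                 "provenance: " + json.dumps(self.provenance)]
        return "\n".join(lines)


def write_report(report: VerdictReport, path: str | Path) -> None:
    """Write the per-cycle table as CSV plus a JSON sidecar at ``path`` + .json."""
    path = Path(path)
    report.to_frame().to_csv(path, index=False)
    Path(str(path) + ".json").write_text(report.to_json())
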