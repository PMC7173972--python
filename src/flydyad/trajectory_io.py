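"""Canonical data model and file I/O for dyad trajectories and behavior bouts.

The on-disk dialects are deliberately simple, column-oriented CSV files
modeled on what a video tracker (per-frame fly ellipses) and a bout
classifier (labeled intervals) export after conversion:

* trajectory CSV — header ``frame,role,x_mm,y_mm,heading_rad``, one row per
  fly per frame, frames contiguous from 0;
* bout CSV — header ``behavior,fly,start_frame,end_frame``, half-open
  0-based frame intervals.

All internal computation is in millimetres and seconds; pixel-unit inputs
are converted by the reader via ``mm_per_px``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArenaConfig",
    "FlyTrack",
    "DyadTrajectory",
    "Bout",
    "BoutTable",
    "FormatError",
    "IntegrityError",
    "read_trajectory",
    "write_trajectory",
    "read_bouts",
    "write_bouts",
    "derive_speed",
    "write_results",
    "read_results",
]

BEHAVIORS = ("lunge", "wing_extension", "headbutt", "orienting", "other")
ROLES = ("tester", "target")


class FormatError(ValueError):
    """The file does not conform to the documented dialect."""


class IntegrityError(ValueError):
    """The file parses but violates a data invariant (gaps, NaNs, bad intervals)."""


@dataclass(frozen=True)
class ArenaConfig:
    """Recording geometry and timing.

    Parameters
    ----------
    fps : float
        Frame rate in Hz (recordings are made at 60 fps).
    arena_diameter : float
        Arena diameter in mm (a well of the 12-well chamber).
    n_frames : int
        Total frame count of the recording.
    mm_per_px : float, optional
        Scale for pixel-unit trajectory files; ``None`` means the file is
        already in mm.
    """

    fps: float = 60.0
    arena_diameter: float = 20.0
    n_frames: int = 36000
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.arena_diameter <= 0:
            raise ValueError(f"arena_diameter must be > 0, got {self.arena_diameter}")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class FlyTrack:
    """Per-frame kinematics of a single fly.

    ``heading`` is head direction in radians, mathematical convention
    (0 = +x, counterclockwise positive), wrapped to (-pi, pi].  ``speed``
    (mm/s) is optional and derivable from positions via :func:`derive_speed`.
    """

    role: str
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    speed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        n = len(self.x)
        if not (len(self.y) == len(self.heading) == n):
            raise ValueError("x, y, heading must have identical length")
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)
            if len(self.speed) != n:
                raise ValueError("speed length mismatch")
        if n and not np.all(np.isfinite(self.heading)):
            raise IntegrityError("non-finite heading values")
        # wrap to (-pi, pi]
        h = np.mod(self.heading + math.pi, 2 * math.pi) - math.pi
        h[h == -math.pi] = math.pi
        self.heading = h

    @property
    def n_frames(self) -> int:
        return len(self.x)


@dataclass
class DyadTrajectory:
    """One tester/target pair plus arena metadata."""

    arena: ArenaConfig
    tester: FlyTrack
    target: FlyTrack

    def __post_init__(self) -> None:
        if self.tester.role != "tester" or self.target.role != "target":
            raise ValueError("roles must be tester and target")
        if self.tester.n_frames != self.arena.n_frames:
            raise IntegrityError(
                f"tester has {self.tester.n_frames} frames, arena expects {self.arena.n_frames}"
            )
        if self.target.n_frames != self.arena.n_frames:
            raise IntegrityError(
                f"target has {self.target.n_frames} frames, arena expects {self.arena.n_frames}"
            )


@dataclass(frozen=True, order=True)
class Bout:
    """A labeled behavior interval, half-open ``[start_frame, end_frame)``."""

    behavior: str
    fly: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame < self.end_frame):
            raise IntegrityError(
                f"invalid bout interval [{self.start_frame}, {self.end_frame})"
            )

    def duration_s(self, fps: float) -> float:
        return (self.end_frame - self.start_frame) / fps

    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class BoutTable:
    """Ordered, non-overlapping collection of bouts.

    Bouts are kept sorted by (behavior, fly, start_frame); same-behavior,
    same-fly bouts never overlap (overlaps are merged on construction).
    ``provenance`` records whether duration filtering has been applied.
    """

    bouts: list[Bout] = field(default_factory=list)
    provenance: str = "raw"

    def __post_init__(self) -> None:
        if self.provenance not in ("raw", "filtered"):
            raise ValueError(f"provenance must be raw|filtered, got {self.provenance!r}")
        self.bouts = _merge_overlaps(self.bouts)

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    def select(self, behavior: str | None = None, fly: str | None = None) -> "BoutTable":
        sel = [
            b
            for b in self.bouts
            if (behavior is None or b.behavior == behavior)
            and (fly is None or b.fly == fly)
        ]
        out = BoutTable.__new__(BoutTable)
        out.bouts = sel
        out.provenance = self.provenance
        return out

    def behaviors(self) -> list[str]:
        return sorted({b.behavior for b in self.bouts})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b.behavior, b.fly, b.start_frame, b.end_frame) for b in self.bouts],
            columns=["behavior", "fly", "start_frame", "end_frame"],
        )


def _merge_overlaps(bouts: Iterable[Bout]) -> list[Bout]:
    """Merge overlapping or touching same-behavior, same-fly intervals."""
    by_key: dict[tuple[str, str], list[Bout]] = {}
    for b in bouts:
        by_key.setdefault((b.behavior, b.fly), []).append(b)
    merged: list[Bout] = []
    for (behavior, fly), group in by_key.items():
        group.sort(key=lambda b: b.start_frame)
        cur_s, cur_e = group[0].start_frame, group[0].end_frame
        for b in group[1:]:
            if b.start_frame <= cur_e:  # overlap or abutment
                cur_e = max(cur_e, b.end_frame)
            else:
                merged.append(Bout(behavior, fly, cur_s, cur_e))
                cur_s, cur_e = b.start_frame, b.end_frame
        merged.append(Bout(behavior, fly, cur_s, cur_e))
    merged.sort()
    return merged


# ---------------------------------------------------------------------------
# trajectory I/O

_TRAJ_COLUMNS = ["frame", "role", "x_mm", "y_mm", "heading_rad"]
_TRAJ_COLUMNS_PX = ["frame", "role", "x_px", "y_px", "heading_rad"]


def read_trajectory(path: str | Path, arena: ArenaConfig | None = None) -> DyadTrajectory:
    """Read a dyad trajectory CSV into a validated :class:`DyadTrajectory`.

    The file must contain contiguous frames from 0 for both roles.  If the
    positional columns are ``x_px,y_px``, ``arena.mm_per_px`` is required and
    positions are converted to mm.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if all(c in cols for c in _TRAJ_COLUMNS):
        xcol, ycol, scale = "x_mm", "y_mm", 1.0
    elif all(c in cols for c in _TRAJ_COLUMNS_PX):
        if arena is None or arena.mm_per_px is None:
            raise FormatError("pixel-unit trajectory requires arena.mm_per_px")
        xcol, ycol, scale = "x_px", "y_px", arena.mm_per_px
    else:
        missing = [c for c in _TRAJ_COLUMNS if c not in cols]
        raise FormatError(f"{path.name}: missing columns {missing}")

    tracks: dict[str, FlyTrack] = {}
    n_frames = None
    for role, sub in df.groupby("role"):
        if role not in ROLES:
            raise FormatError(f"unknown role {role!r}")
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        expected = np.arange(len(frames))
        if not np.array_equal(frames, expected):
            gaps = sorted(set(range(int(frames.max()) + 1)) - set(frames.tolist()))
            raise IntegrityError(f"{role}: non-contiguous frames, gap at {gaps[:5]}")
        x = sub[xcol].to_numpy(dtype=float) * scale
        y = sub[ycol].to_numpy(dtype=float) * scale
        bad = np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))
        if bad.size:
            raise IntegrityError(f"{role}: NaN coordinates at frames {bad[:10].tolist()}")
        tracks[role] = FlyTrack(role=role, x=x, y=y, heading=sub["heading_rad"].to_numpy(dtype=float))
        if n_frames is None:
            n_frames = len(frames)
        elif n_frames != len(frames):
            raise IntegrityError("tester and target frame counts differ")
    if set(tracks) != set(ROLES):
        raise FormatError(f"file must contain exactly roles {ROLES}, got {sorted(tracks)}")
    if arena is None:
        arena = ArenaConfig(n_frames=n_frames)
    elif arena.n_frames != n_frames:
        arena = replace(arena, n_frames=n_frames)
    return DyadTrajectory(arena=arena, tester=tracks["tester"], target=tracks["target"])


def write_trajectory(dyad: DyadTrajectory, path: str | Path) -> None:
    rows = []
    for track in (dyad.tester, dyad.target):
        for t in range(track.n_frames):
            rows.append((t, track.role, track.x[t], track.y[t], track.heading[t]))
    pd.DataFrame(rows, columns=_TRAJ_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bout I/O

_BOUT_COLUMNS = ["behavior", "fly", "start_frame", "end_frame"]


def read_bouts(path: str | Path) -> BoutTable:
    """Read a bout CSV; overlapping same-behavior same-fly intervals merge."""
    df = pd.read_csv(path)
    missing = [c for c in _BOUT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing columns {missing}")
    bouts = [
        Bout(str(r.behavior), str(r.fly), int(r.start_frame), int(r.end_frame))
        for r in df.itertuples()
    ]
    return BoutTable(bouts=bouts, provenance="raw")


def write_bouts(table: BoutTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# kinematics

def derive_speed(track: FlyTrack, fps: float, smooth_window: int = 1) -> np.ndarray:
    """Centroid speed (mm/s) by backward finite difference, optionally smoothed.

    ``speed[t] = fps * ||p[t] - p[t-1]||`` for t >= 1; ``speed[0]`` copies
    ``speed[1]`` (0 for a single-frame track).  A boxcar of odd width
    ``smooth_window`` is applied afterwards (1 = no smoothing); edges use a
    shrinking window so the output length equals the input length.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    n = track.n_frames
    if n == 1:
        return np.zeros(1)
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    speed = np.empty(n)
    speed[1:] = fps * np.hypot(dx, dy)
    speed[0] = speed[1]
    if smooth_window > 1:
        half = smooth_window // 2
        csum = np.concatenate(([0.0], np.cumsum(speed)))
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        speed = (csum[hi] - csum[lo]) / (hi - lo)
    return speed


# ---------------------------------------------------------------------------
# results I/O (lossless round-trip for tabular summaries)

def write_results(df: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write a tidy results table as CSV or JSON (records orient).

    The format is inferred from the suffix when not given.  Both encodings
    carry the same fields so they agree field-by-field.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        payload = {"columns": list(df.columns), "records": df.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=1, default=_json_default) + "\n")
    else:
        raise ValueError(f"unsupported results format {fmt!r}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_results(path: str | Path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["records"], columns=payload["columns"])
    raise ValueError(f"unsupported results format {fmt!r}")
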