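"""The "time orienting" interaction metric.

A tester fly is *orienting* toward the target in a frame when all three
conditions hold:

1. the target centroid lies within ±``max_angle`` (default 60°) of the
   tester's heading direction,
2. the centroid-to-centroid distance is within ``max_dist`` (default 5 mm,
   about two body lengths), and
3. the tester's moving speed exceeds ``min_speed`` (default 0.1 mm/s).

Conditions 2-3 suppress frames where a stationary (often grooming) tester
happens to face a passing target.  Maximal runs of qualifying frames become
bouts; runs shorter than ``min_bout`` (default 200 ms, guarding against
head/tail flips and other tracking noise) are discarded.  Angle and distance
comparisons are inclusive (≤); the speed comparison is strict (>).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .trajectory_io import Bout, BoutTable, DyadTrajectory, derive_speed

__all__ = [
    "OrientingParams",
    "orienting_mask",
    "segment_orienting_bouts",
    "time_orienting",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrientingParams:
    """Thresholds of the orienting predicate and the bout-duration filter."""

    max_angle: float = 60.0  # degrees, inclusive
    max_dist: float = 5.0  # mm, inclusive
    min_speed: float = 0.1  # mm/s, strict
    min_bout: float = 200.0  # ms; bouts strictly shorter are discarded
    speed_smooth_window: int = 1  # frames; 1 = raw backward differences

    def __post_init__(self) -> None:
        if not (0 < self.max_angle <= 180):
            raise ValueError("max_angle must be in (0, 180] degrees")
        for name in ("max_dist", "min_speed", "min_bout"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def orienting_mask(
    dyad: DyadTrajectory, params: OrientingParams = OrientingParams()
) -> np.ndarray:
    """Per-frame boolean orienting predicate.

    Coincident centroids make the bearing undefined; the angle condition is
    then treated as satisfied (the distance condition is already met at
    distance 0) and the frames are logged.
    """
    tester, target = dyad.tester, dyad.target
    speed = tester.speed
    if speed is None:
        speed = derive_speed(tester, dyad.arena.fps, params.speed_smooth_window)

    dx = target.x - tester.x
    dy = target.y - tester.y
    dist = np.hypot(dx, dy)

    coincident = dist == 0.0
    if np.any(coincident):
        logger.warning(
            "bearing undefined at %d coincident-centroid frames; angle condition "
            "treated as satisfied",
            int(coincident.sum()),
        )
    bearing = np.arctan2(dy, dx)
    rel = bearing - tester.heading
    rel = np.mod(rel + math.pi, 2 * math.pi) - math.pi  # wrap to [-pi, pi)
    angle_ok = np.abs(rel) <= math.radians(params.max_angle)
    angle_ok |= coincident

    return angle_ok & (dist <= params.max_dist) & (speed > params.min_speed)


def segment_orienting_bouts(
    mask: np.ndarray,
    fps: float,
    params: OrientingParams = OrientingParams(),
    fly: str = "tester",
) -> BoutTable:
    """Maximal runs of true frames, with sub-``min_bout`` runs discarded.

    A run of exactly ``min_bout`` milliseconds is kept — only strictly
    shorter bouts are removed.
    """
    mask = np.asarray(mask, dtype=bool)
    min_frames = params.min_bout / 1000.0 * fps
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    bouts = [
        Bout("orienting", fly, int(s), int(e))
        for s, e in zip(starts, ends)
        if (e - s) >= min_frames
    ]
    return BoutTable(bouts=bouts, provenance="filtered")


def time_orienting(
    bouts: BoutTable, fps: float, n_frames: int
) -> tuple[float, np.ndarray]:
    """Total orienting seconds and a per-minute series.

    Each minute receives the seconds of orienting whose frames fall in that
    minute, so bouts spanning a minute boundary are split and the per-minute
    values sum to the total.
    """
    frames_per_min = int(round(60 * fps))
    n_minutes = int(math.ceil(n_frames / frames_per_min))
    per_min = np.zeros(max(n_minutes, 1))
    total_frames = 0
    for b in bouts:
        total_frames += b.n_frames()
        first = b.start_frame // frames_per_min
        last = (b.end_frame - 1) // frames_per_min
        for m in range(first, last + 1):
            lo = max(b.start_frame, m * frames_per_min)
            hi = min(b.end_frame, (m + 1) * frames_per_min)
            per_min[m] += (hi - lo) / fps
    return total_frames / fps, per_min
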