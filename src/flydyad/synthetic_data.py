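"""Synthetic dyads, bout processes, LED indicators, and voxel stacks.

Every pipeline stage is testable without raw video: the generator emulates
60 fps dyad kinematics in a circular arena, the 10-min LED paradigm (1 min
pre, three 1-min stimulation blocks separated by 2-min ISIs),
state-dependent Poisson bout emission with log-normal durations, and image
stacks containing rasterized spheres of known voxel volume.

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64, so a fixed seed reproduces identical outputs across platforms.
Trajectory generation also returns the frame-by-frame ground truth of the
orienting predicate, computed with scalar arithmetic during generation so
it is an independent check on the vectorized analysis path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .orienting import OrientingParams
from .stim_schedule import Paradigm, StimulusSchedule
from .trajectory_io import ArenaConfig, Bout, BoutTable, DyadTrajectory, FlyTrack
from .volume_quant import VoxelStack

__all__ = [
    "KinematicsParams",
    "BoutModel",
    "SimSpec",
    "ScriptSegment",
    "simulate_dyad",
    "scripted_dyad",
    "simulate_bouts",
    "simulate_indicator",
    "simulate_voxel_stack",
]


@dataclass(frozen=True)
class KinematicsParams:
    """Correlated-random-walk parameters for one fly.

    Steps are drawn per frame with mean ``step_mean`` mm (≈5 mm/s at
    60 fps) and SD ``step_sd``; heading diffuses with SD ``turn_sd`` rad per
    frame.  During approach epochs (entered with probability
    ``approach_p_enter`` per frame, left with ``approach_p_exit``) the
    tester's heading is steered toward the target with gain
    ``approach_gain``; walls reflect.
    """

    step_mean: float = 0.085  # mm/frame
    step_sd: float = 0.05
    turn_sd: float = 0.25  # rad/frame
    approach_p_enter: float = 0.004
    approach_p_exit: float = 0.01
    approach_gain: float = 0.3


@dataclass(frozen=True)
class BoutModel:
    """Per-behavior Poisson rates (events/min) per window and durations.

    ``rates`` maps behavior -> {window id -> rate}; durations are i.i.d.
    log-normal with the given median (ms) and log-SD.  Default medians sit
    above the duration filters (lunge 120 ms > 50 ms floor, wing extension
    800 ms > 100 ms floor) so filtering is exercised by dedicated
    sub-threshold scenarios rather than by accident.
    """

    rates: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "lunge": {1: 2.0, 2: 2.0, 3: 2.0, 4: 2.0},
            "wing_extension": {1: 5.0, 2: 5.0, 3: 5.0, 4: 5.0},
        }
    )
    duration_median_ms: dict[str, float] = field(
        default_factory=lambda: {
            "lunge": 120.0,
            "headbutt": 150.0,
            "wing_extension": 800.0,
            "orienting": 1000.0,
        }
    )
    duration_log_sd: float = 0.35

    def scaled(self, behavior: str, window: int, factor: float) -> "BoutModel":
        """A copy with one behavior's rate in one window multiplied."""
        rates = {b: dict(w) for b, w in self.rates.items()}
        rates[behavior][window] = rates[behavior][window] * factor
        return replace(self, rates=rates)


@dataclass(frozen=True)
class SimSpec:
    """One simulated recording: arena, kinematics, bout model, paradigm."""

    seed: int = 0
    arena: ArenaConfig = field(
        default_factory=lambda: ArenaConfig(fps=60.0, arena_diameter=20.0, n_frames=36000)
    )
    kinematics: KinematicsParams = field(default_factory=KinematicsParams)
    bout_model: BoutModel = field(default_factory=BoutModel)
    paradigm: Paradigm = field(default_factory=Paradigm)
    orienting: OrientingParams = field(default_factory=OrientingParams)

    def __post_init__(self) -> None:
        if self.arena.arena_diameter < 2.0:
            raise ValueError("arena too small for two flies")


def _wrap(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def simulate_dyad(spec: SimSpec) -> tuple[DyadTrajectory, np.ndarray]:
    """Correlated-random-walk dyad plus ground-truth orienting mask.

    The truth mask applies the orienting predicate (angle, distance, speed
    thresholds from ``spec.orienting``; backward-difference speed) frame by
    frame with scalar math.  Run-length filtering is *not* applied here —
    the mask is the raw per-frame predicate.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.arena.n_frames
    radius = spec.arena.arena_diameter / 2.0
    kp = spec.kinematics

    pos = np.empty((2, n, 2))
    heads = np.empty((2, n))
    # independent starting poses in the inner half of the arena
    for f in range(2):
        r = radius * 0.5 * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        pos[f, 0] = (r * math.cos(th), r * math.sin(th))
        heads[f, 0] = rng.uniform(-math.pi, math.pi)

    approaching = False
    for t in range(1, n):
        if approaching:
            if rng.uniform() < kp.approach_p_exit:
                approaching = False
        elif rng.uniform() < kp.approach_p_enter:
            approaching = True
        for f in range(2):
            h = heads[f, t - 1] + rng.normal(0.0, kp.turn_sd)
            if f == 0 and approaching:
                to_target = math.atan2(
                    pos[1, t - 1, 1] - pos[0, t - 1, 1],
                    pos[1, t - 1, 0] - pos[0, t - 1, 0],
                )
                h = h + kp.approach_gain * _wrap(to_target - h)
            h = _wrap(h)
            step = max(0.0, rng.normal(kp.step_mean, kp.step_sd))
            x = pos[f, t - 1, 0] + step * math.cos(h)
            y = pos[f, t - 1, 1] + step * math.sin(h)
            rho = math.hypot(x, y)
            if rho > radius:  # reflect off the wall, turn inward
                x *= (2 * radius - rho) / rho
                y *= (2 * radius - rho) / rho
                h = _wrap(math.atan2(-y, -x) + rng.normal(0.0, 0.5))
            pos[f, t] = (x, y)
            heads[f, t] = h

    dyad = DyadTrajectory(
        arena=spec.arena,
        tester=FlyTrack("tester", pos[0, :, 0], pos[0, :, 1], heads[0]),
        target=FlyTrack("target", pos[1, :, 0], pos[1, :, 1], heads[1]),
    )

    truth = np.zeros(n, dtype=bool)
    op = spec.orienting
    max_ang = math.radians(op.max_angle)
    for t in range(n):
        tprev = max(t, 1)  # speed[0] copies speed[1]
        sp = spec.arena.fps * math.hypot(
            pos[0, tprev, 0] - pos[0, tprev - 1, 0],
            pos[0, tprev, 1] - pos[0, tprev - 1, 1],
        )
        dx = pos[1, t, 0] - pos[0, t, 0]
        dy = pos[1, t, 1] - pos[0, t, 1]
        dist = math.hypot(dx, dy)
        if dist == 0.0:
            ang_ok = True
        else:
            ang_ok = abs(_wrap(math.atan2(dy, dx) - heads[0, t])) <= max_ang
        truth[t] = ang_ok and dist <= op.max_dist and sp > op.min_speed
    return dyad, truth


@dataclass(frozen=True)
class ScriptSegment:
    """A piecewise-constant-geometry segment of a scripted dyad.

    Both flies translate together at ``speed`` mm/s along the tester
    heading, so relative bearing, distance, and tester speed are constant
    within the segment and the orienting predicate's truth is known
    analytically.
    """

    duration_s: float
    tester_xy: tuple[float, float]
    heading: float  # radians
    target_xy: tuple[float, float]
    speed: float  # mm/s

    def qualifies(self, params: OrientingParams) -> bool:
        dx = self.target_xy[0] - self.tester_xy[0]
        dy = self.target_xy[1] - self.tester_xy[1]
        dist = math.hypot(dx, dy)
        ang_ok = dist == 0.0 or abs(
            _wrap(math.atan2(dy, dx) - self.heading)
        ) <= math.radians(params.max_angle)
        return ang_ok and dist <= params.max_dist and self.speed > params.min_speed


def scripted_dyad(
    segments: list[ScriptSegment], fps: float = 60.0
) -> DyadTrajectory:
    """Deterministic dyad trajectory assembled from scripted segments."""
    if not segments:
        raise ValueError("need at least one segment")
    xs_t, ys_t, hs_t, xs_g, ys_g = [], [], [], [], []
    for seg in segments:
        n = int(round(seg.duration_s * fps))
        step = seg.speed / fps
        for k in range(n):
            dx = k * step * math.cos(seg.heading)
            dy = k * step * math.sin(seg.heading)
            xs_t.append(seg.tester_xy[0] + dx)
            ys_t.append(seg.tester_xy[1] + dy)
            hs_t.append(seg.heading)
            xs_g.append(seg.target_xy[0] + dx)
            ys_g.append(seg.target_xy[1] + dy)
    n_frames = len(xs_t)
    span = 2 * max(
        max(map(abs, xs_t + xs_g), default=1.0), max(map(abs, ys_t + ys_g), default=1.0)
    )
    arena = ArenaConfig(fps=fps, arena_diameter=max(span + 10.0, 20.0), n_frames=n_frames)
    return DyadTrajectory(
        arena=arena,
        tester=FlyTrack("tester", np.array(xs_t), np.array(ys_t), np.array(hs_t)),
        target=FlyTrack("target", np.array(xs_g), np.array(ys_g), np.zeros(n_frames)),
    )


def simulate_bouts(
    spec: SimSpec,
    schedule: StimulusSchedule,
    fly: str = "tester",
    rng: np.random.Generator | None = None,
) -> tuple[BoutTable, dict[str, dict[int, float]]]:
    """Window-inhomogeneous Poisson bout onsets with log-normal durations.

    Within each window interval, onsets arrive at that window's rate
    (events/min); durations are i.i.d. log-normal and bouts are truncated
    at the end of the recording.  Overlapping same-behavior bouts merge in
    the returned table.  The true rates used are returned alongside.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    fps = schedule.fps
    n_frames = spec.arena.n_frames
    bm = spec.bout_model
    bouts: list[Bout] = []
    for behavior in sorted(bm.rates):
        window_rates = bm.rates[behavior]
        med = bm.duration_median_ms[behavior]
        for w in sorted(schedule.window_map):
            rate = window_rates.get(w, 0.0)
            if rate <= 0:
                continue
            for s, e in schedule.window_map[w]:
                minutes = (e - s) / fps / 60.0
                k = rng.poisson(rate * minutes)
                if k == 0:
                    continue
                onsets = np.sort(rng.integers(s, e, size=k))
                dur_ms = np.exp(rng.normal(math.log(med), bm.duration_log_sd, size=k))
                for onset, d in zip(onsets, dur_ms):
                    end = min(n_frames, int(onset) + max(1, int(round(d / 1000.0 * fps))))
                    if end > onset:
                        bouts.append(Bout(behavior, fly, int(onset), end))
    return BoutTable(bouts=bouts, provenance="raw"), {
        b: dict(w) for b, w in bm.rates.items()
    }


def simulate_indicator(
    schedule: StimulusSchedule,
    n_frames: int,
    baseline: float = 0.0,
    on_level: float = 100.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Infrared indicator-LED intensity series: high during LED-on frames."""
    series = np.full(n_frames, baseline, dtype=float)
    for s, e in schedule.window_map.get(2, []):
        series[s:min(e, n_frames)] = on_level
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        series = np.clip(series + rng.normal(0.0, noise_sd, size=n_frames), 0.0, None)
    return series


def simulate_voxel_stack(
    blobs: list[tuple[tuple[float, float, float], float, float]],
    shape: tuple[int, int, int] = (32, 32, 16),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VoxelStack, dict]:
    """Rasterized spheres of known voxel volume, plus Gaussian noise.

    ``blobs`` is a list of ``(center, radius, intensity)`` in voxel index
    units.  Overlapping blobs take the maximum intensity; the returned
    truth carries the union voxel count and per-blob counts.
    """
    grid = np.zeros(shape, dtype=float)
    ix, iy, iz = np.indices(shape)
    union = np.zeros(shape, dtype=bool)
    per_blob = []
    for (cx, cy, cz), radius, intensity in blobs:
        if not (0 <= cx < shape[0] and 0 <= cy < shape[1] and 0 <= cz < shape[2]):
            raise ValueError(f"blob center {(cx, cy, cz)} outside stack bounds {shape}")
        inside = (ix - cx) ** 2 + (iy - cy) ** 2 + (iz - cz) ** 2 <= radius**2
        per_blob.append(int(inside.sum()))
        union |= inside
        grid = np.where(inside, np.maximum(grid, intensity), grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid = np.clip(grid + rng.normal(0.0, noise_sd, size=shape), 0.0, None)
    truth = {
        "union_voxels": int(union.sum()),
        "union_volume_um3": float(union.sum() * np.prod(voxel_size)),
        "per_blob_voxels": per_blob,
    }
    return VoxelStack(intensities=grid, voxel_size=voxel_size), truth
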