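"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately scalar, loop-based reimplementations of
the predicates under test — they share no code with the vectorized package
paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from flydyad import ArenaConfig, Bout, BoutTable, DyadTrajectory, FlyTrack, OrientingParams


def wrap_angle(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def brute_force_orienting(dyad: DyadTrajectory, params: OrientingParams) -> np.ndarray:
    """Per-frame orienting predicate via scalar dot-product arithmetic."""
    n = dyad.arena.n_frames
    fps = dyad.arena.fps
    tx, ty = dyad.tester.x, dyad.tester.y
    gx, gy = dyad.target.x, dyad.target.y
    hd = dyad.tester.heading
    cos_max = math.cos(math.radians(params.max_angle))
    out = np.zeros(n, dtype=bool)
    for t in range(n):
        tp = max(t, 1)
        sp = fps * math.sqrt((tx[tp] - tx[tp - 1]) ** 2 + (ty[tp] - ty[tp - 1]) ** 2)
        dx, dy = gx[t] - tx[t], gy[t] - ty[t]
        dist = math.sqrt(dx * dx + dy * dy)
        if dist == 0.0:
            ang_ok = True
        else:
            # dot product between unit heading vector and unit bearing vector
            dot = (math.cos(hd[t]) * dx + math.sin(hd[t]) * dy) / dist
            ang_ok = dot >= cos_max - 1e-12
        out[t] = ang_ok and dist <= params.max_dist and sp > params.min_speed
    return out


def random_dyad(rng: np.random.Generator, n_frames: int, fps: float = 60.0) -> DyadTrajectory:
    """I.i.d. random poses in a 20 mm arena — adversarial for the predicate."""
    arena = ArenaConfig(fps=fps, arena_diameter=20.0, n_frames=n_frames)

    def track(role: str) -> FlyTrack:
        r = 10.0 * np.sqrt(rng.uniform(size=n_frames))
        th = rng.uniform(0, 2 * math.pi, size=n_frames)
        return FlyTrack(
            role,
            r * np.cos(th),
            r * np.sin(th),
            rng.uniform(-math.pi, math.pi, size=n_frames),
        )

    return DyadTrajectory(arena=arena, tester=track("tester"), target=track("target"))


def random_bout_table(
    rng: np.random.Generator,
    n_bouts: int,
    n_frames: int,
    behaviors=("lunge", "wing_extension", "headbutt"),
    max_len: int = 120,
) -> BoutTable:
    bouts = []
    for _ in range(n_bouts):
        start = int(rng.integers(0, n_frames - 1))
        length = int(rng.integers(1, max_len))
        bouts.append(
            Bout(
                str(rng.choice(behaviors)),
                "tester",
                start,
                min(n_frames, start + length),
            )
        )
    return BoutTable(bouts=bouts, provenance="raw")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
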