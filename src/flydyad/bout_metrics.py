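"""Post-processing of classifier bout tables: duration filters and minute bins.

Extremely short classifier detections are almost always false positives and
are discarded by behavior-specific duration floors (lunge and headbutt
50 ms, wing extension 100 ms; strict "<" discards, so boundary-equal bouts
survive).  The amount of behavior is the number of bouts for lunges and
headbutts and the total duration in seconds for wing extensions, binned per
minute for quantification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import BoutTable

__all__ = ["BoutFilterParams", "MinuteBins", "ConfigurationError", "filter_bouts", "bin_per_minute", "default_mode"]

logger = logging.getLogger(__name__)

#: behavior -> quantification mode the analysis uses by default
_DEFAULT_MODES = {
    "lunge": "count",
    "headbutt": "count",
    "wing_extension": "duration",
    "orienting": "duration",
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BoutFilterParams:
    """Per-behavior minimum duration (ms) below which bouts are discarded."""

    min_duration_ms: dict[str, float] = field(
        default_factory=lambda: {
            "lunge": 50.0,
            "headbutt": 50.0,
            "wing_extension": 100.0,
            "orienting": 200.0,
        }
    )

    def __post_init__(self) -> None:
        for k, v in self.min_duration_ms.items():
            if v <= 0:
                raise ConfigurationError(f"min_duration_ms[{k!r}] must be > 0")


@dataclass
class MinuteBins:
    """Per-minute amounts of one behavior for one fly.

    ``mode`` is ``count`` (bouts/min, attributed to the minute of the start
    frame) or ``duration`` (s/min, split across minutes by frame
    membership).
    """

    behavior: str
    fly: str
    mode: str
    values: np.ndarray
    n_minutes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("count", "duration"):
            raise ValueError(f"mode must be count|duration, got {self.mode!r}")
        if len(self.values) != self.n_minutes:
            raise ValueError("values length must equal n_minutes")
        if np.any(self.values < 0):
            raise ValueError("minute bins must be nonnegative")


def default_mode(behavior: str) -> str:
    """The quantification mode conventionally used for a behavior."""
    return _DEFAULT_MODES.get(behavior, "count")


def filter_bouts(
    bouts: BoutTable, params: BoutFilterParams, fps: float
) -> BoutTable:
    """Discard bouts strictly shorter than their behavior's duration floor.

    Requires a raw table (filtering is applied exactly once in the pipeline;
    re-filtering an already-filtered table is a usage error).  Every behavior
    present must have a configured threshold — there is no silent default.
    """
    if bouts.provenance != "raw":
        raise ValueError("filter_bouts expects provenance='raw'")
    unknown = [b for b in bouts.behaviors() if b not in params.min_duration_ms]
    if unknown:
        raise ConfigurationError(f"no duration threshold configured for {unknown}")
    kept = [
        b
        for b in bouts
        if b.duration_s(fps) * 1000.0 >= params.min_duration_ms[b.behavior]
    ]
    n_dropped = len(bouts) - len(kept)
    if n_dropped:
        logger.info("filter_bouts: discarded %d of %d bouts", n_dropped, len(bouts))
    out = BoutTable(bouts=kept, provenance="filtered")
    return out


def bin_per_minute(
    bouts: BoutTable,
    behavior: str,
    mode: str,
    fps: float,
    n_frames: int,
    fly: str | None = None,
) -> MinuteBins:
    """Bin one behavior's amount per minute.

    count mode assigns each bout to the minute containing its start frame (a
    lunge is momentary, ~0.05-0.2 s, so no double counting); duration mode
    splits bout seconds across minutes by frame membership, conserving the
    total.
    """
    if bouts.provenance != "filtered":
        raise ValueError("bin_per_minute expects provenance='filtered'")
    if behavior == "wing_extension" and mode == "count":
        logger.warning("counting wing_extension bouts; durations are conventional")
    frames_per_min = int(round(60 * fps))
    n_minutes = int(math.ceil(n_frames / frames_per_min))
    values = np.zeros(max(n_minutes, 1))
    sel = bouts.select(behavior=behavior, fly=fly)
    for b in sel:
        if mode == "count":
            values[b.start_frame // frames_per_min] += 1
        else:
            first = b.start_frame // frames_per_min
            last = (b.end_frame - 1) // frames_per_min
            for m in range(first, last + 1):
                lo = max(b.start_frame, m * frames_per_min)
                hi = min(b.end_frame, (m + 1) * frames_per_min)
                values[m] += (hi - lo) / fps
    return MinuteBins(
        behavior=behavior,
        fly=fly or "tester",
        mode=mode,
        values=values,
        n_minutes=max(n_minutes, 1),
    )
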