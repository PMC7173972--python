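"""The optogenetic stimulation paradigm and analysis windows 1-4.

The 10-minute paradigm is 1 min pre-stimulation (window 1), then three
blocks of 1 min LED-on (window 2, 3 min total) each followed by a 2 min
inter-stimulus interval (ISI, 6 min total).  Frames are aligned on the
frame in which the infrared indicator LED first turns on.

Window 3/4 composition is configurable:

* ``isi_split`` (default): window 3 pools the first half of each ISI
  (its first minute under the standard 2-min ISI), window 4 the second
  half — the only four-window partition of the paradigm consistent with
  early/late ISI effects;
* ``isi_pooled``: window 3 pools all ISI minutes and window 4 is empty.

Per-window amounts are normalized to per-minute rates so windows of unequal
total duration are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bout_metrics import MinuteBins, default_mode
from .trajectory_io import BoutTable

__all__ = [
    "Paradigm",
    "StimulusSchedule",
    "WindowSummary",
    "AlignmentError",
    "detect_led_onset",
    "build_schedule",
    "pool_windows",
]

Interval = tuple[int, int]  # half-open frame interval


class AlignmentError(RuntimeError):
    pass


@dataclass(frozen=True)
class Paradigm:
    """Timing of the LED stimulation paradigm (seconds)."""

    pre_s: float = 60.0
    n_blocks: int = 3
    on_s: float = 60.0
    isi_s: float = 120.0
    led_frequency_hz: float | None = None  # metadata only
    total_s: float = 600.0

    def __post_init__(self) -> None:
        expected = self.pre_s + self.n_blocks * (self.on_s + self.isi_s)
        if abs(expected - self.total_s) > 1e-9:
            raise ValueError(
                f"paradigm timing inconsistent: pre + blocks*(on+isi) = {expected}"
                f" != total_s = {self.total_s}"
            )


@dataclass
class StimulusSchedule:
    """Frame-level map of the paradigm: window id (1-4) -> frame intervals."""

    onset_frame: int
    fps: float
    window_map: dict[int, list[Interval]]
    window_mode: str
    paradigm: Paradigm = field(default_factory=Paradigm)

    def window_minutes(self, window: int) -> float:
        return sum(e - s for s, e in self.window_map.get(window, [])) / self.fps / 60.0

    @property
    def n_frames(self) -> int:
        return max((e for ivs in self.window_map.values() for _, e in ivs), default=0)

    def frames_in(self, window: int) -> np.ndarray:
        """Boolean membership mask over [0, n_frames)."""
        mask = np.zeros(self.n_frames, dtype=bool)
        for s, e in self.window_map.get(window, []):
            mask[s:e] = True
        return mask


@dataclass
class WindowSummary:
    """Per fly × behavior × window per-minute rates for one pair.

    ``rates`` is a tidy DataFrame with columns
    ``pair_id, genotype, fly, behavior, window, rate``; ``window_mode`` is
    carried so downstream outputs always state how windows 3/4 were formed.
    """

    rates: pd.DataFrame
    window_mode: str
    pair_id: str = "pair0"
    genotype: str = "unknown"

    def rate(self, fly: str, behavior: str, window: int) -> float:
        df = self.rates
        sel = df[(df.fly == fly) & (df.behavior == behavior) & (df.window == window)]
        if sel.empty:
            raise KeyError(f"no rate for ({fly}, {behavior}, window {window})")
        return float(sel.rate.iloc[0])


def detect_led_onset(indicator: np.ndarray, threshold: float) -> int:
    """First frame whose indicator-LED intensity exceeds ``threshold``."""
    indicator = np.asarray(indicator, dtype=float)
    above = np.flatnonzero(indicator > threshold)
    if above.size == 0:
        raise AlignmentError("no frame with indicator intensity above threshold")
    return int(above[0])


def build_schedule(
    onset_frame: int,
    fps: float,
    paradigm: Paradigm = Paradigm(),
    window_mode: str = "isi_split",
    n_frames: int | None = None,
) -> StimulusSchedule:
    """Map the paradigm onto frame intervals given the first LED-on frame.

    Window 1 is the pre-stimulation minute ending at ``onset_frame``; window
    2 pools the LED-on blocks; windows 3/4 partition the ISIs according to
    ``window_mode``.  The onset must leave room for the full pre-stimulation
    period, and the schedule must fit in ``n_frames`` when given.
    """
    if window_mode not in ("isi_split", "isi_pooled"):
        raise ValueError(f"unknown window_mode {window_mode!r}")
    pre_f = int(round(paradigm.pre_s * fps))
    on_f = int(round(paradigm.on_s * fps))
    isi_f = int(round(paradigm.isi_s * fps))
    if onset_frame < pre_f:
        raise AlignmentError(
            f"onset frame {onset_frame} leaves less than {paradigm.pre_s} s of pre-stimulation"
        )
    window_map: dict[int, list[Interval]] = {1: [(onset_frame - pre_f, onset_frame)], 2: [], 3: [], 4: []}
    cursor = onset_frame
    for _ in range(paradigm.n_blocks):
        window_map[2].append((cursor, cursor + on_f))
        cursor += on_f
        if window_mode == "isi_split":
            half = isi_f // 2
            window_map[3].append((cursor, cursor + half))
            window_map[4].append((cursor + half, cursor + isi_f))
        else:
            window_map[3].append((cursor, cursor + isi_f))
        cursor += isi_f
    if n_frames is not None and cursor > n_frames:
        raise AlignmentError(
            f"schedule extends to frame {cursor} but recording has {n_frames} frames"
        )
    return StimulusSchedule(
        onset_frame=onset_frame,
        fps=fps,
        window_map={k: v for k, v in window_map.items() if v},
        window_mode=window_mode,
        paradigm=paradigm,
    )


def pool_windows(
    bouts: BoutTable,
    schedule: StimulusSchedule,
    behavior: str,
    mode: str | None = None,
    fly: str = "tester",
    pair_id: str = "pair0",
    genotype: str = "unknown",
) -> WindowSummary:
    """Pool one behavior's amount over each window, normalized per minute.

    Count mode attributes each bout to the window containing its start
    frame; duration mode splits bout seconds across window boundaries by
    frame membership.  A window with zero pooled minutes is reported as
    missing (NaN rate).
    """
    if mode is None:
        mode = default_mode(behavior)
    sel = bouts.select(behavior=behavior, fly=fly)
    rows = []
    for w in sorted(schedule.window_map):
        minutes = schedule.window_minutes(w)
        if minutes == 0:
            rows.append((pair_id, genotype, fly, behavior, w, float("nan")))
            continue
        amount = 0.0
        for b in sel:
            for s, e in schedule.window_map[w]:
                if mode == "count":
                    if s <= b.start_frame < e:
                        amount += 1
                else:
                    overlap = min(b.end_frame, e) - max(b.start_frame, s)
                    if overlap > 0:
                        amount += overlap / schedule.fps
        rows.append((pair_id, genotype, fly, behavior, w, amount / minutes))
    rates = pd.DataFrame(
        rows, columns=["pair_id", "genotype", "fly", "behavior", "window", "rate"]
    )
    return WindowSummary(
        rates=rates, window_mode=schedule.window_mode, pair_id=pair_id, genotype=genotype
    )


def pool_minute_bins(bins: MinuteBins, schedule: StimulusSchedule) -> dict[int, float]:
    """Pool per-minute bins into windows when minutes align with windows.

    Requires every window interval to start and end on a minute boundary of
    the binning grid (true when the recording starts exactly one
    pre-stimulation period before onset).
    """
    frames_per_min = int(round(60 * schedule.fps))
    out: dict[int, float] = {}
    for w, ivs in schedule.window_map.items():
        amount, minutes = 0.0, 0
        for s, e in ivs:
            if s % frames_per_min or e % frames_per_min:
                raise ValueError(
                    "window intervals are not minute-aligned; pool from the bout table instead"
                )
            m0, m1 = s // frames_per_min, e // frames_per_min
            amount += float(np.sum(bins.values[m0:m1]))
            minutes += m1 - m0
        out[w] = amount / minutes if minutes else float("nan")
    return out
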