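"""Bout-level recall/precision evaluation of behavior classifiers.

Classifier bout tables are compared against human-annotated ("true") bout
tables.  A true bout counts as detected when a predicted bout overlaps at
least ``min_overlap`` of its frames (default: any overlap, i.e. >= 1
frame); a predicted bout with no single frame of overlap against any true
bout is a false positive.

Recall = (true bouts detected) / (total true bouts).

Precision here is (true bouts detected) / [(total detected bouts) + (false
positive bouts)] — note the denominator counts false positives on top of
the full detection count, so it is never larger than the conventional
tp / detected, which is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .trajectory_io import BoutTable

__all__ = ["MatchCounts", "match_bouts", "recall", "precision", "evaluation_report"]


@dataclass(frozen=True)
class MatchCounts:
    """Bout-matching tallies for one behavior."""

    n_true: int
    n_detected: int
    tp: int
    fp: int

    def __post_init__(self) -> None:
        if self.tp > self.n_true:
            raise ValueError("tp cannot exceed n_true")
        if self.fp > self.n_detected:
            raise ValueError("fp cannot exceed n_detected")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def match_bouts(
    true_bouts: BoutTable, pred_bouts: BoutTable, min_overlap: float = 0.0
) -> MatchCounts:
    """Count detected true bouts and false-positive predictions.

    Both tables must contain a single behavior (and the same one).
    ``min_overlap`` in (0, 1] requires that fraction of the true bout's
    frames to be covered; 0 means any overlap (>= 1 frame).
    """
    if not (0.0 <= min_overlap <= 1.0):
        raise ValueError("min_overlap must be in [0, 1]")
    for t in (true_bouts, pred_bouts):
        if len(t.behaviors()) > 1:
            raise ValueError(f"mixed behaviors in one call: {t.behaviors()}")
    bt = true_bouts.behaviors()
    bp = pred_bouts.behaviors()
    if bt and bp and bt != bp:
        raise ValueError(f"behavior mismatch: {bt} vs {bp}")

    tv = list(true_bouts)
    pv = list(pred_bouts)
    tp = 0
    for t in tv:
        need = max(1, min_overlap * t.n_frames()) if min_overlap > 0 else 1
        if any(
            _overlap(t.start_frame, t.end_frame, p.start_frame, p.end_frame) >= need
            for p in pv
        ):
            tp += 1
    fp = sum(
        1
        for p in pv
        if not any(
            _overlap(t.start_frame, t.end_frame, p.start_frame, p.end_frame) >= 1
            for t in tv
        )
    )
    return MatchCounts(n_true=len(tv), n_detected=len(pv), tp=tp, fp=fp)


def recall(counts: MatchCounts) -> float:
    """Fraction of true bouts detected; NaN when no true bouts exist."""
    if counts.n_true == 0:
        return float("nan")
    return counts.tp / counts.n_true


def precision(counts: MatchCounts, conventional: bool = False) -> float:
    """Detected-true bouts over the (FP-augmented) detection count.

    With ``conventional=True`` the denominator is just the detection count.
    NaN when the denominator is zero.
    """
    denom = counts.n_detected if conventional else counts.n_detected + counts.fp
    if denom == 0:
        return float("nan")
    return counts.tp / denom


def evaluation_report(
    true_bouts: BoutTable, pred_bouts: BoutTable, min_overlap: float = 0.0
) -> pd.DataFrame:
    """Per-behavior evaluation table.

    Columns: ``behavior, n_true, n_detected, tp, fp, recall, precision,
    precision_conventional``.
    """
    behaviors = sorted(set(true_bouts.behaviors()) | set(pred_bouts.behaviors()))
    rows = []
    for beh in behaviors:
        c = match_bouts(
            true_bouts.select(behavior=beh), pred_bouts.select(behavior=beh), min_overlap
        )
        rows.append(
            (beh, c.n_true, c.n_detected, c.tp, c.fp, recall(c), precision(c), precision(c, conventional=True))
        )
    return pd.DataFrame(
        rows,
        columns=[
            "behavior",
            "n_true",
            "n_detected",
            "tp",
            "fp",
            "recall",
            "precision",
            "precision_conventional",
        ],
    )
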