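"""End-to-end drivers: one pair, then a cohort, to statistics and tables.

``run_pair`` reproduces the per-pair post-processing chain: derive tester
speed, evaluate the orienting predicate and segment it into bouts, apply
the duration filters to classifier bouts, align frames on the indicator
LED, and pool everything into per-window per-minute rates.  ``run_cohort``
stacks pairs, runs the within-window and between-genotype statistical
suites, and classifies responders.

Pairs flagged for exclusion (a fly killed at introduction, a wing stuck
extended, identities untrackable) are manual observations; they enter via
an exclusion list and are skipped with a logged reason, never inferred.

Every output row carries the config digest and the window mode so results
are traceable to their parameters.  The whole pipeline is a pure function
of (inputs, config): reruns produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior_stats import ResponderRules, classify_responders, window_comparison_suite
from .bout_metrics import default_mode, filter_bouts
from .config import AnalysisConfig
from .orienting import orienting_mask, segment_orienting_bouts
from .stim_schedule import (
    StimulusSchedule,
    WindowSummary,
    build_schedule,
    detect_led_onset,
    pool_windows,
)
from .trajectory_io import BoutTable, DyadTrajectory

__all__ = ["PairInput", "CohortResult", "run_pair", "run_cohort", "write_cohort_outputs"]

logger = logging.getLogger(__name__)


@dataclass
class PairInput:
    """Everything the pipeline needs for one tester/target pair."""

    trajectory: DyadTrajectory
    bouts: BoutTable
    pair_id: str
    genotype: str = "unknown"
    indicator: np.ndarray | None = None  # per-frame LED intensity
    onset_frame: int | None = None  # alternative to an indicator series


@dataclass
class CohortResult:
    summaries: list[WindowSummary]
    window_stats: pd.DataFrame
    genotype_stats: pd.DataFrame
    responders: pd.DataFrame
    rates: pd.DataFrame  # tidy figures-ready table
    excluded: list[str] = field(default_factory=list)


def _resolve_onset(pair: PairInput, config: AnalysisConfig) -> int:
    if pair.onset_frame is not None:
        return pair.onset_frame
    if pair.indicator is not None:
        return detect_led_onset(pair.indicator, config.led_threshold)
    # recording started one pre-stimulation period before the LED
    return int(round(config.paradigm.pre_s * config.arena.fps))


def run_pair(
    pair: PairInput,
    config: AnalysisConfig = AnalysisConfig(),
    behaviors: list[str] | None = None,
) -> WindowSummary:
    """Per-pair window summary: orienting + filtered classifier behaviors."""
    dyad = pair.trajectory
    if dyad.arena.n_frames != dyad.tester.n_frames:
        raise ValueError("trajectory frame counts inconsistent")
    for b in pair.bouts:
        if b.end_frame > dyad.arena.n_frames:
            raise ValueError(
                f"bout [{b.start_frame},{b.end_frame}) exceeds the "
                f"{dyad.arena.n_frames}-frame recording"
            )
    fps = dyad.arena.fps

    mask = orienting_mask(dyad, config.orienting)
    orient_bouts = segment_orienting_bouts(mask, fps, config.orienting)
    filtered = filter_bouts(pair.bouts, config.bout_filter, fps)
    logger.info(
        "%s: %d orienting bouts, %d/%d classifier bouts kept",
        pair.pair_id, len(orient_bouts), len(filtered), len(pair.bouts),
    )

    onset = _resolve_onset(pair, config)
    schedule = build_schedule(
        onset, fps, config.paradigm, config.window_mode, n_frames=dyad.arena.n_frames
    )

    if behaviors is None:
        behaviors = sorted(set(filtered.behaviors()) | {"orienting"})
    frames = []
    for beh in behaviors:
        source = orient_bouts if beh == "orienting" else filtered
        ws = pool_windows(
            source, schedule, beh, mode=default_mode(beh),
            fly="tester", pair_id=pair.pair_id, genotype=pair.genotype,
        )
        frames.append(ws.rates)
    rates = pd.concat(frames, ignore_index=True)
    return WindowSummary(
        rates=rates, window_mode=config.window_mode,
        pair_id=pair.pair_id, genotype=pair.genotype,
    )


def run_cohort(
    pairs: list[PairInput],
    config: AnalysisConfig = AnalysisConfig(),
    behaviors: list[str] | None = None,
    exclusions: set[str] | None = None,
    test_genotype: str | None = None,
    responder_behaviors: tuple[str, ...] = (),
    responder_rules: ResponderRules = ResponderRules(),
) -> CohortResult:
    """Cohort-level statistics over per-pair window summaries.

    Within-genotype window comparisons (windows 1-3, paired signed-rank
    post-hoc) run per behavior and genotype; between-genotype comparisons
    (window-2 rates, Mann-Whitney post-hoc against each control) run when
    the cohort has >= 2 genotypes.  ``responder_behaviors`` selects which
    behaviors get the window-2 responder classification.
    """
    if not pairs:
        raise ValueError("empty cohort")
    exclusions = exclusions or set()
    excluded = [p.pair_id for p in pairs if p.pair_id in exclusions]
    for pid in excluded:
        logger.info("pair %s excluded (listed in exclusion file)", pid)
    kept = [p for p in pairs if p.pair_id not in exclusions]
    if not kept:
        raise ValueError("all pairs excluded")

    summaries = [run_pair(p, config, behaviors) for p in kept]
    if behaviors is None:
        behaviors = sorted(summaries[0].rates.behavior.unique())

    genotypes = sorted({s.genotype for s in summaries})
    window_rows, genotype_rows = [], []
    for beh in behaviors:
        for geno in genotypes:
            group = [s for s in summaries if s.genotype == geno]
            if len(group) >= 2:
                rep = window_comparison_suite(group, beh, design="within_windows")
                df = rep.to_frame()
                df.insert(0, "genotype", geno)
                df.insert(0, "behavior", beh)
                window_rows.append(df)
        if len(genotypes) >= 2:
            rep = window_comparison_suite(
                summaries, beh, design="between_genotypes",
                test_genotype=test_genotype, window=2,
            )
            df = rep.to_frame()
            df.insert(0, "behavior", beh)
            genotype_rows.append(df)

    window_stats = pd.concat(window_rows, ignore_index=True) if window_rows else pd.DataFrame()
    genotype_stats = pd.concat(genotype_rows, ignore_index=True) if genotype_rows else pd.DataFrame()

    responder_frames = [
        classify_responders(summaries, beh, responder_rules)
        for beh in responder_behaviors
    ]
    responders = (
        pd.concat(responder_frames, ignore_index=True)
        if responder_frames
        else pd.DataFrame(columns=["pair_id", "genotype", "behavior", "responder"])
    )

    rates = pd.concat([s.rates for s in summaries], ignore_index=True)
    rates["window_mode"] = config.window_mode
    rates["config"] = config.digest()
    for df in (window_stats, genotype_stats, responders):
        if not df.empty:
            df["window_mode"] = config.window_mode
            df["config"] = config.digest()
    return CohortResult(
        summaries=summaries,
        window_stats=window_stats,
        genotype_stats=genotype_stats,
        responders=responders,
        rates=rates,
        excluded=excluded,
    )


def write_cohort_outputs(result: CohortResult, outdir: str | Path) -> dict[str, Path]:
    """Write the tidy rate table, stats report, and responder table.

    Outputs are deterministic functions of the result (sorted keys, no
    timestamps), so reruns on identical inputs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rates": outdir / "window_rates.csv",
        "stats": outdir / "stats_report.json",
        "responders": outdir / "responders.csv",
    }
    result.rates.to_csv(paths["rates"], index=False)
    report = {
        "window_stats": result.window_stats.to_dict(orient="records"),
        "genotype_stats": result.genotype_stats.to_dict(orient="records"),
        "excluded_pairs": result.excluded,
    }
    paths["stats"].write_text(json.dumps(report, indent=1, sort_keys=True, default=str) + "\n")
    result.responders.to_csv(paths["responders"], index=False)
    return paths
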