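"""Experiment configuration: one YAML file drives every module default."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .bout_metrics import BoutFilterParams
from .orienting import OrientingParams
from .stim_schedule import Paradigm
from .trajectory_io import ArenaConfig

__all__ = ["AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable analysis parameters in one place.

    ``led_threshold`` is the indicator-intensity level above which the LED
    counts as on; ``window_mode`` chooses the ISI split for windows 3/4 and
    is propagated into every output for provenance.
    """

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    paradigm: Paradigm = field(default_factory=Paradigm)
    orienting: OrientingParams = field(default_factory=OrientingParams)
    bout_filter: BoutFilterParams = field(default_factory=BoutFilterParams)
    window_mode: str = "isi_split"
    led_threshold: float = 50.0

    def to_dict(self) -> dict:
        return {
            "arena": asdict(self.arena),
            "paradigm": asdict(self.paradigm),
            "orienting": asdict(self.orienting),
            "bout_filter": asdict(self.bout_filter),
            "window_mode": self.window_mode,
            "led_threshold": self.led_threshold,
        }

    def digest(self) -> str:
        """Short stable hash of the configuration, stamped on outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML (defaults when absent)."""
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "arena" in raw:
        kwargs["arena"] = ArenaConfig(**raw["arena"])
    if "paradigm" in raw:
        kwargs["paradigm"] = Paradigm(**raw["paradigm"])
    if "orienting" in raw:
        kwargs["orienting"] = OrientingParams(**raw["orienting"])
    if "bout_filter" in raw:
        kwargs["bout_filter"] = BoutFilterParams(**raw["bout_filter"])
    for key in ("window_mode", "led_threshold"):
        if key in raw:
            kwargs[key] = raw[key]
    return AnalysisConfig(**kwargs)
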