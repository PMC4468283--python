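"""Analysis configuration.

Every tunable threshold of the signal-processing chain lives here, grouped by
stage, with the defaults documented in docs/methods.md.  A single JSON document
with one section per stage overrides any subset of them.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class FramingConfig:
    frame_length: float = 0.016  # s; 256 samples at 16 kHz
    frame_shift: float = 0.010   # s; 160 samples at 16 kHz


@dataclass
class VoicingConfig:
    f0_min: float = 50.0    # Hz; lower search bound, covers pathological male voices
    f0_max: float = 500.0   # Hz; upper bound, covers pathological female voices
    v_thresh: float = 0.45  # normalized-autocorrelation peak threshold
    e_thresh: float = 0.1   # energy threshold, relative to median frame energy
    median_window: int = 5  # frames, F0 median smoothing
    octave_tolerance: float = 0.04  # relative tolerance for octave-jump folding
    subharmonic_ratio: float = 0.87  # shortest correlation peak within this
    # fraction of the best peak wins the lag choice (guards octave-down errors)


@dataclass
class ProsodyConfig:
    filler_labels: tuple[str, ...] = ("äh", "ähm", "hm")
    window_words: int = 15   # words per "global" feature window
    min_tail_words: int = 8  # shorter tails merge into the previous window
    min_cycles_per_section: int = 4  # peaks needed before a section yields jitter


@dataclass
class EggConfig:
    invert: bool = False        # set when increasing contact lowers the trace
    contact_level: float = 0.3  # normalized-amplitude threshold for the closed phase
    fx_min: float = 50.0        # Hz; cycles outside [fx_min, fx_max] are discarded
    fx_max: float = 500.0
    peak_rel_threshold: float = 0.3  # fraction of the rolling 95th dEGG percentile
    rolling_window: float = 0.5      # s; span of the rolling percentile


@dataclass
class ModelConfig:
    C: float = 1.0
    epsilon: float = 0.001
    folds: int = 10
    tol: float = 1e-3          # maximal KKT violation at convergence
    stall_limit: int = 5       # non-improving best-first expansions before stopping
    min_frequency: float = 0.5  # cross-fold selection frequency needed for the final set


@dataclass
class AnalysisConfig:
    framing: FramingConfig = field(default_factory=FramingConfig)
    voicing: VoicingConfig = field(default_factory=VoicingConfig)
    prosody: ProsodyConfig = field(default_factory=ProsodyConfig)
    egg: EggConfig = field(default_factory=EggConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "AnalysisConfig":
        cfg = cls()
        for section_name, values in doc.items():
            if not hasattr(cfg, section_name):
                raise KeyError(f"unknown config section: {section_name!r}")
            section = getattr(cfg, section_name)
            for key, value in values.items():
                if not hasattr(section, key):
                    raise KeyError(f"unknown config key: {section_name}.{key}")
                if isinstance(getattr(section, key), tuple):
                    value = tuple(value)
                setattr(section, key, value)
        return cfg

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["prosody"]["filler_labels"] = list(doc["prosody"]["filler_labels"])
        return doc
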