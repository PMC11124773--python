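"""Pipeline configuration: every tunable of every stage in one place.

Defaults are the working values of the detection pipeline: 16 kHz
working rate, 200-8000 Hz third-order Butterworth front end, 410/160
framing, 7.5 % relative energy threshold with 6-frame padding and 0.12 s
merging, 35 % overlap labelling, MIX P2 features, C = 0.05, 2000-epoch
MLP cap, 5-fold CV.  Configs serialise to flat YAML and hash stably so
every artifact can record exactly what produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # signal front end
    working_rate_hz: int = 16000
    bandpass_low_hz: float = 200.0
    bandpass_high_hz: float = 8000.0
    bandpass_order: int = 3
    zero_phase: bool = False
    bandpass_before_resample: bool = True
    # framing / detection
    frame_length: int = 410
    hop: int = 160
    rel_threshold: float = 0.075
    pad_frames: int = 6
    merge_gap_s: float = 0.12
    min_overlap: float = 0.35
    overlap_denominator: str = "event"
    # features
    pattern_id: str = "MIX_P2"
    pre_emphasis_coeff: float = 0.97
    mfcc_include_c0: bool = False
    # classifiers
    model_kind: str = "elm"
    svm_c: float = 0.05
    mlp_max_epochs: int = 2000
    mlp_grad_tol: float = 1e-6
    n_svm: int = 5
    n_mlp: int = 5
    learner_order: str = "alternate"
    # evaluation
    k_folds: int = 5
    standardize: bool = True
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.bandpass_low_hz < self.bandpass_high_hz):
            raise ValueError("require 0 < bandpass_low_hz < bandpass_high_hz")
        if not (0 < self.hop <= self.frame_length):
            raise ValueError("require 0 < hop <= frame_length")
        if not (0 < self.rel_threshold < 1):
            raise ValueError("rel_threshold must be a fraction in (0, 1)")
        if not (0 <= self.min_overlap <= 1):
            raise ValueError("min_overlap must be in [0, 1]")
        if self.pad_frames < 0 or self.merge_gap_s < 0:
            raise ValueError("pad_frames and merge_gap_s must be non-negative")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.model_kind not in ("svm", "mlp", "elm"):
            raise ValueError("model_kind must be one of svm, mlp, elm")
        if self.overlap_denominator not in ("event", "annotation", "union"):
            raise ValueError("overlap_denominator must be event, annotation or union")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration."""
        payload = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.as_dict(), sort_keys=True), encoding="utf-8"
        )
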