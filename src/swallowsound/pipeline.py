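"""End-to-end orchestration: audio -> events -> features -> CV report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .event_detection import (
    EnergyTrack,
    FrameSpec,
    LoudEvent,
    detect_loud_events,
    detection_recall,
    frame_signal,
    label_events,
    log_energy,
    write_events,
)
from .evaluation import CVReport, cross_validate
from .features import feature_names, featurize_events
from .signal_io import (
    AnnotationInterval,
    AudioRecording,
    bandpass,
    read_annotations,
    read_wav,
    resample,
)

__all__ = [
    "PipelineResult",
    "preprocess",
    "detect",
    "detect_and_label",
    "featurize",
    "run_full_pipeline",
]

log = logging.getLogger("swallowsound")


def preprocess(rec: AudioRecording, config: PipelineConfig) -> AudioRecording:
    """Band-pass front end and resampling to the working rate.

    At the native 44.1 kHz rate the full 200-8000 Hz band-pass applies
    before down-sampling (the default order); at the working rate the
    8 kHz edge sits on Nyquist, where the design degenerates to a 200 Hz
    high-pass of the same order.
    """
    steps = (
        ("bandpass", "resample") if config.bandpass_before_resample else ("resample", "bandpass")
    )
    for step in steps:
        if step == "bandpass":
            high = min(config.bandpass_high_hz, rec.sample_rate / 2.0)
            rec = bandpass(
                rec,
                low_hz=config.bandpass_low_hz,
                high_hz=high,
                order=config.bandpass_order,
                zero_phase=config.zero_phase,
            )
        else:
            rec = resample(rec, config.working_rate_hz)
    return rec


def _frame_spec(config: PipelineConfig) -> FrameSpec:
    return FrameSpec(
        frame_length=config.frame_length,
        hop=config.hop,
        sample_rate=config.working_rate_hz,
    )


def detect(rec: AudioRecording, config: PipelineConfig) -> list[LoudEvent]:
    """Preprocess a recording and detect its loud events (unlabelled)."""
    processed = preprocess(rec, config)
    spec = _frame_spec(config)
    frames = frame_signal(processed.samples, spec)
    if len(frames) == 0:
        raise ValueError(f"{rec.source_id}: recording shorter than one frame")
    track = EnergyTrack(values=log_energy(frames), spec=spec)
    return detect_loud_events(
        track,
        rel_threshold=config.rel_threshold,
        pad_frames=config.pad_frames,
        merge_gap_s=config.merge_gap_s,
    )


def detect_and_label(
    rec: AudioRecording,
    annotations: list[AnnotationInterval],
    config: PipelineConfig,
) -> list[LoudEvent]:
    events = detect(rec, config)
    return label_events(
        events,
        annotations,
        min_overlap=config.min_overlap,
        denominator=config.overlap_denominator,
    )


def featurize(
    rec: AudioRecording, events: list[LoudEvent], config: PipelineConfig
) -> np.ndarray:
    """Event feature matrix under the configured pattern (preprocessing included)."""
    processed = preprocess(rec, config)
    return featurize_events(
        processed,
        events,
        pattern_id=config.pattern_id,
        frame_spec=_frame_spec(config),
        pre_emphasis_coeff=config.pre_emphasis_coeff,
        include_c0=config.mfcc_include_c0,
    )


@dataclass(frozen=True)
class PipelineResult:
    """Everything the full pipeline computed, plus provenance."""

    report: CVReport
    features: np.ndarray
    labels: np.ndarray
    events_per_recording: dict[str, list[LoudEvent]]
    recall: float
    config_hash: str


def _collect_scene_paths(scene_dir: Path) -> list[tuple[Path, Path]]:
    """Pair WAV files with their annotation TSVs inside a scene directory."""
    pairs: list[tuple[Path, Path]] = []
    for wav in sorted(scene_dir.glob("*.wav")):
        ann = wav.with_name(wav.stem + "_annotations.tsv")
        if not ann.exists():
            raise FileNotFoundError(
                f"labelling stage: missing annotation file {ann} for {wav}"
            )
        pairs.append((wav, ann))
    if not pairs:
        raise FileNotFoundError(f"no WAV files found in {scene_dir}")
    return pairs


def run_full_pipeline(
    config: PipelineConfig,
    inputs: str | Path | list[tuple[Path, Path]],
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Detect, label, featurise and cross-validate over a set of recordings.

    ``inputs`` is a scene directory (WAVs with ``*_annotations.tsv``
    sidecars) or an explicit list of (wav, annotations) path pairs.  When
    ``out_dir`` is given, events, features, and the report are written
    there, each stamped with the config hash and seed.
    """
    if isinstance(inputs, (str, Path)):
        pairs = _collect_scene_paths(Path(inputs))
    else:
        pairs = [(Path(w), Path(a)) for w, a in inputs]

    all_features: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    events_per_recording: dict[str, list[LoudEvent]] = {}
    recalls: list[float] = []
    for wav_path, ann_path in pairs:
        try:
            rec = read_wav(wav_path)
            annotations = read_annotations(ann_path)
            events = detect_and_label(rec, annotations, config)
            feats = featurize(rec, events, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on {wav_path.name}: {exc}") from exc
        events_per_recording[rec.source_id] = events
        all_features.append(feats)
        all_labels.append(np.array([ev.label for ev in events], dtype=np.int64))
        if annotations:
            recalls.append(
                detection_recall(events, annotations, min_overlap=config.min_overlap)
            )
        log.info(
            "%s: %d events (%d swallow)",
            rec.source_id,
            len(events),
            int(all_labels[-1].sum()),
        )

    features = np.vstack(all_features)
    labels = np.concatenate(all_labels)
    report = cross_validate(
        features,
        labels,
        model_kind=config.model_kind,
        k=config.k_folds,
        seed=config.seed,
        standardize=config.standardize,
        stratify=config.stratify,
        svm_c=config.svm_c,
        mlp_max_epochs=config.mlp_max_epochs,
        mlp_grad_tol=config.mlp_grad_tol,
        n_svm=config.n_svm,
        n_mlp=config.n_mlp,
        learner_order=config.learner_order,
    )
    recall = float(np.mean(recalls)) if recalls else float("nan")
    result = PipelineResult(
        report=report,
        features=features,
        labels=labels,
        events_per_recording=events_per_recording,
        recall=recall,
        config_hash=config.config_hash(),
    )
    if out_dir is not None:
        _write_artifacts(result, config, Path(out_dir))
    return result


def _write_artifacts(
    result: PipelineResult, config: PipelineConfig, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": result.config_hash, "seed": config.seed}
    for source_id, events in result.events_per_recording.items():
        write_events(out_dir / f"{source_id}_events.tsv", events)
    frame = pd.DataFrame(result.features, columns=feature_names(config.pattern_id))
    frame.insert(0, "label", result.labels)
    frame.to_csv(out_dir / "features.csv", index=False)
    (out_dir / "features.schema.json").write_text(
        json.dumps(
            {**provenance, "pattern_id": config.pattern_id,
             "columns": ["label", *feature_names(config.pattern_id)]},
            indent=2,
        ),
        encoding="utf-8",
    )
    report_payload = {
        **provenance,
        "annotation_recall": result.recall,
        "cv": result.report.as_dict(),
    }
    (out_dir / "report.json").write_text(
        json.dumps(report_payload, indent=2, sort_keys=True), encoding="utf-8"
    )
    config.to_yaml(out_dir / "config.yaml")
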