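"""Loud-event detection by relative log-energy thresholding.

The filtered signal is cut into frames of 410 samples with a 160-sample
hop (25.6 ms / 10 ms at 16 kHz) and each frame's log energy is computed.
A frame is *loud* when its linear energy exceeds a fraction (7.5 % by
default) of the maximum frame energy of the recording, so detection is
invariant to the overall recording gain.  Runs of loud frames become loud
events, each event is padded by 6 frames (0.06 s) per side, and events
separated by less than 0.12 s are merged.  Loud events are then labelled
swallow / non-swallow by their overlap with expert swallow annotations
(>= 35 % of the event duration inside annotated swallow time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .signal_io import AnnotationInterval

__all__ = [
    "FrameSpec",
    "EnergyTrack",
    "LoudEvent",
    "SWALLOW",
    "NON_SWALLOW",
    "frame_signal",
    "log_energy",
    "detect_loud_events",
    "label_events",
    "detection_recall",
    "read_events",
    "write_events",
]

SWALLOW = 1
NON_SWALLOW = 0

#: Additive floor inside the log so silent frames stay finite.
LOG_ENERGY_EPS = 1e-12


@dataclass(frozen=True)
class FrameSpec:
    """Framing geometry: frame width, hop, and the rate they refer to."""

    frame_length: int = 410
    hop: int = 160
    sample_rate: int = 16000

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.frame_length):
            raise ValueError(
                f"require 0 < hop <= frame_length, got hop={self.hop}, "
                f"frame_length={self.frame_length}"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def hop_s(self) -> float:
        return self.hop / self.sample_rate

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.frame_length:
            return 0
        return (n_samples - self.frame_length) // self.hop + 1


@dataclass(frozen=True)
class EnergyTrack:
    """Per-frame natural-log energy values for one recording."""

    values: np.ndarray
    spec: FrameSpec

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise ValueError("energy track must be 1-D")
        if not np.all(np.isfinite(values)):
            raise ValueError("energy track contains non-finite values")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class LoudEvent:
    """A contiguous run of loud frames; frame indices are inclusive."""

    start_frame: int
    end_frame: int
    start_s: float
    end_s: float
    label: int | None = None  # SWALLOW, NON_SWALLOW or None when unlabelled

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")

    @classmethod
    def from_frames(
        cls,
        start_frame: int,
        end_frame: int,
        spec: FrameSpec,
        label: int | None = None,
    ) -> "LoudEvent":
        start_s = start_frame * spec.hop / spec.sample_rate
        end_s = (end_frame * spec.hop + spec.frame_length) / spec.sample_rate
        return cls(start_frame, end_frame, start_s, end_s, label)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def frame_signal(samples: np.ndarray, spec: FrameSpec) -> np.ndarray:
    """Slice a signal into overlapping frames (one frame per row).

    Frame ``i`` covers samples ``[i*hop, i*hop + frame_length)``; a signal
    shorter than one frame yields zero frames.
    """
    x = np.asarray(samples, dtype=np.float64)
    n = spec.n_frames(len(x))
    if n == 0:
        return np.empty((0, spec.frame_length))
    strided = np.lib.stride_tricks.sliding_window_view(x, spec.frame_length)
    return strided[:: spec.hop][:n].copy()


def log_energy(frames: np.ndarray, eps: float = LOG_ENERGY_EPS) -> np.ndarray:
    """Natural log of per-frame energy: ln(sum_k x_k^2 + eps)."""
    frames = np.asarray(frames, dtype=np.float64)
    return np.log(np.sum(frames * frames, axis=-1) + eps)


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def merge_events(
    spans: list[tuple[int, int]], spec: FrameSpec, merge_gap_s: float
) -> list[tuple[int, int]]:
    """Merge frame spans whose inter-event gap is below ``merge_gap_s``.

    The gap between consecutive spans is the number of frames strictly
    between them times the hop period.  Merging runs to fixpoint, so the
    result is sorted and pairwise separated by at least the threshold.
    """
    spans = sorted(spans)
    changed = True
    while changed:
        changed = False
        merged: list[tuple[int, int]] = []
        for span in spans:
            if merged:
                prev = merged[-1]
                gap_s = (span[0] - prev[1] - 1) * spec.hop / spec.sample_rate
                if gap_s < merge_gap_s:
                    merged[-1] = (prev[0], max(prev[1], span[1]))
                    changed = True
                    continue
            merged.append(span)
        spans = merged
    return spans


def detect_loud_events(
    track: EnergyTrack,
    rel_threshold: float = 0.075,
    pad_frames: int = 6,
    merge_gap_s: float = 0.12,
) -> list[LoudEvent]:
    """Detect loud events on an energy track.

    A frame is loud iff its linear energy exceeds ``rel_threshold`` times
    the maximum linear frame energy of the track (on the log scale:
    log-energy > ln(rel_threshold) + max log-energy).  Runs of loud frames
    are padded by ``pad_frames`` per side (clipped to the track) and then
    merged whenever the remaining gap is shorter than ``merge_gap_s``.
    Returned events are disjoint, sorted, and unlabelled.
    """
    if len(track) == 0:
        raise ValueError("cannot detect events on an empty energy track")
    spec = track.spec
    loud = track.values > math.log(rel_threshold) + np.max(track.values)
    spans = _runs_of_true(loud)
    last = len(track) - 1
    padded = [
        (max(0, s - pad_frames), min(last, e + pad_frames)) for s, e in spans
    ]
    merged = merge_events(padded, spec, merge_gap_s)
    return [LoudEvent.from_frames(s, e, spec) for s, e in merged]


def _interval_union(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _overlap_with_union(
    lo: float, hi: float, union: list[tuple[float, float]]
) -> float:
    return sum(max(0.0, min(hi, b) - max(lo, a)) for a, b in union)


def label_events(
    events: list[LoudEvent],
    annotations: list[AnnotationInterval],
    min_overlap: float = 0.35,
    denominator: str = "event",
) -> list[LoudEvent]:
    """Label each loud event swallow / non-swallow against annotations.

    All supplied annotations are treated as swallow intervals and merged
    into a union.  An event is a swallow when its overlap fraction reaches
    ``min_overlap`` (boundary inclusive).  ``denominator`` selects what
    the intersection is divided by: the event duration (default), the
    overlapping annotation's duration ("annotation"), or the duration of
    the union of event and annotations ("union").
    """
    union = _interval_union([(a.start_s, a.end_s) for a in annotations])
    out: list[LoudEvent] = []
    for ev in events:
        inter = _overlap_with_union(ev.start_s, ev.end_s, union)
        if denominator == "event":
            frac = inter / ev.duration_s
        elif denominator == "annotation":
            frac = max(
                (
                    max(0.0, min(ev.end_s, a.end_s) - max(ev.start_s, a.start_s))
                    / a.duration_s
                    for a in annotations
                ),
                default=0.0,
            )
        elif denominator == "union":
            union_dur = sum(b - a for a, b in union)
            total = union_dur + ev.duration_s - inter
            frac = inter / total if total > 0 else 0.0
        else:
            raise ValueError(f"unknown overlap denominator {denominator!r}")
        label = SWALLOW if frac >= min_overlap else NON_SWALLOW
        out.append(replace(ev, label=label))
    return out


def detection_recall(
    events: list[LoudEvent],
    truth: list[AnnotationInterval],
    min_overlap: float = 0.35,
) -> float:
    """Fraction of ground-truth intervals recovered by the detector.

    An interval counts as recovered when at least ``min_overlap`` of its
    duration is covered by detected events.  Annotated sounds too quiet to
    cross the energy threshold show up here as misses; they produce no
    loud event of their own.
    """
    if not truth:
        raise ValueError("no ground-truth intervals supplied")
    union = _interval_union([(e.start_s, e.end_s) for e in events])
    hit = sum(
        1
        for iv in truth
        if _overlap_with_union(iv.start_s, iv.end_s, union) / iv.duration_s
        >= min_overlap
    )
    return hit / len(truth)


def write_events(path: str | Path, events: list[LoudEvent]) -> None:
    """Write events as TSV: start_s, end_s, start_frame, end_frame, label."""
    lines = ["start_s\tend_s\tstart_frame\tend_frame\tlabel"]
    for ev in events:
        lab = "" if ev.label is None else str(ev.label)
        lines.append(
            f"{ev.start_s:.6f}\t{ev.end_s:.6f}\t{ev.start_frame}\t{ev.end_frame}\t{lab}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_events(path: str | Path) -> list[LoudEvent]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    events: list[LoudEvent] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        start_s, end_s, start_f, end_f, lab = line.split("\t")
        events.append(
            LoudEvent(
                start_frame=int(start_f),
                end_frame=int(end_f),
                start_s=float(start_s),
                end_s=float(end_s),
                label=int(lab) if lab else None,
            )
        )
    return events
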