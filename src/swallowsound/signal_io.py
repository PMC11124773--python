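"""Audio and annotation I/O plus the band-pass front end.

Recordings are mono PCM WAV files; clinical throat-microphone audio is
captured at 44.1 kHz / 16 bit and down-sampled to a 16 kHz working rate.
A third-order Butterworth band-pass (200-8000 Hz) isolates the band where
swallowing sounds carry their energy.  Annotations travel as Audacity-style
label tracks: UTF-8 TSV with ``start_s<TAB>end_s<TAB>label`` per line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "AudioRecording",
    "AnnotationInterval",
    "read_wav",
    "write_wav",
    "read_annotations",
    "write_annotations",
    "resample",
    "bandpass",
]

#: PCM16 full-scale divisor; int16 sample i maps to float i / 32768.
PCM16_SCALE = 32768.0


@dataclass(frozen=True)
class AudioRecording:
    """A mono audio signal with its sample rate.

    Parameters
    ----------
    samples : ndarray
        1-D float array, amplitudes nominally in [-1, 1].
    sample_rate : int
        Sampling frequency in Hz, strictly positive.
    source_id : str
        Opaque identifier of the recording's origin (file stem, scene id).
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"expected mono (1-D) samples, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if int(self.sample_rate) <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class AnnotationInterval:
    """A labelled time interval on a recording's timeline (seconds)."""

    start_s: float
    end_s: float
    label: str = "swallow"

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start_s}, {self.end_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def read_wav(path: str | Path) -> AudioRecording:
    """Read a mono PCM WAV file into an :class:`AudioRecording`.

    Integer samples are scaled to [-1, 1) by the full-scale value of their
    bit depth (32768 for PCM16).  Multi-channel files raise rather than
    being silently down-mixed.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"{path} is not a readable WAV file: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(
            f"{path} has {data.shape[1]} channels; only mono input is supported"
        )
    if data.dtype == np.int16:
        samples = data / PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype} in {path}")
    return AudioRecording(samples=samples, sample_rate=int(rate), source_id=path.stem)


def write_wav(path: str | Path, rec: AudioRecording) -> None:
    """Write a recording as mono PCM16 WAV.

    Float samples are scaled by 32768 and rounded to the nearest integer,
    so a file read with :func:`read_wav` round-trips bit-exactly.
    """
    scaled = np.rint(rec.samples * PCM16_SCALE)
    clipped = np.clip(scaled, -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), rec.sample_rate, clipped)


def read_annotations(path: str | Path) -> list[AnnotationInterval]:
    """Read an Audacity-style label track (TSV: start_s, end_s, label)."""
    intervals: list[AnnotationInterval] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least two tab-separated fields")
        label = parts[2] if len(parts) > 2 else ""
        intervals.append(AnnotationInterval(float(parts[0]), float(parts[1]), label))
    return intervals


def write_annotations(path: str | Path, intervals: list[AnnotationInterval]) -> None:
    lines = [f"{iv.start_s:.6f}\t{iv.end_s:.6f}\t{iv.label}" for iv in intervals]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def resample(rec: AudioRecording, target_rate: int) -> AudioRecording:
    """Resample to ``target_rate`` Hz with a polyphase anti-aliasing filter.

    Same-rate input is returned unchanged.  Duration is preserved to within
    one sample period.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == rec.sample_rate:
        return rec
    g = math.gcd(target_rate, rec.sample_rate)
    out = sps.resample_poly(rec.samples, target_rate // g, rec.sample_rate // g)
    return replace(rec, samples=out, sample_rate=target_rate)


def butter_bandpass_sos(
    low_hz: float, high_hz: float, sample_rate: int, order: int = 3
) -> np.ndarray:
    """Design the 3rd-order Butterworth band-pass in second-order sections.

    When ``high_hz`` coincides with the Nyquist frequency the upper edge is
    vacuous and the design degenerates; a high-pass of the same order at
    ``low_hz`` is returned instead.
    """
    nyq = sample_rate / 2.0
    if not (0.0 < low_hz < high_hz):
        raise ValueError(f"require 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz > nyq:
        raise ValueError(
            f"upper cutoff {high_hz} Hz exceeds Nyquist {nyq} Hz at rate {sample_rate}"
        )
    if high_hz == nyq:
        return sps.butter(order, low_hz, btype="highpass", fs=sample_rate, output="sos")
    return sps.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=sample_rate, output="sos"
    )


def bandpass(
    rec: AudioRecording,
    low_hz: float = 200.0,
    high_hz: float = 8000.0,
    order: int = 3,
    zero_phase: bool = False,
) -> AudioRecording:
    """Apply the Butterworth band-pass front end.

    Default is a causal single forward pass, which a real-time detector
    could implement; ``zero_phase=True`` switches to forward-backward
    filtering (doubling the effective order).
    """
    sos = butter_bandpass_sos(low_hz, high_hz, rec.sample_rate, order=order)
    if zero_phase:
        out = sps.sosfiltfilt(sos, rec.samples)
    else:
        out = sps.sosfilt(sos, rec.samples)
    return replace(rec, samples=np.asarray(out, dtype=np.float64))
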