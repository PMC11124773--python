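"""MFCC / MFMC frame features and their statistic-pattern pooling.

Per frame (410 samples, Hamming-windowed, zero-padded to a 1024-point
FFT) two acoustic descriptions are computed from a 40-channel mel filter
bank:

* **MFCC** - log mel-filter-bank energies of the *power* spectrum followed
  by an orthonormal type-II DCT; coefficients c1..c12 are kept (c0, which
  only carries overall level, is dropped).
* **MFMC** - log mel-filter-bank outputs of the *amplitude* spectrum used
  directly, without DCT; 40 values per frame.

A loud event spans several frames; each coefficient's trajectory over the
event is pooled into five basic statistics (mean, standard deviation,
median, range, skewness) and, optionally, the same five statistics of its
frame-to-frame first differences ("dynamic features").  Fourteen named
feature patterns select which statistics and which base features enter
the event vector; their dimensions range from 12 (MFCC P1) to 520
(MIX P2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft

from .event_detection import FrameSpec, LoudEvent, frame_signal
from .signal_io import AudioRecording

__all__ = [
    "MelFilterBank",
    "FeaturePatternSpec",
    "PATTERNS",
    "STAT_ORDER",
    "pre_emphasis",
    "build_mel_filterbank",
    "mfcc_frames",
    "mfmc_frames",
    "event_statistics",
    "assemble_pattern",
    "featurize_events",
    "feature_names",
]

STAT_ORDER = ("mean", "sd", "median", "range", "skewness")

#: Floor applied to filter-bank outputs before the log.
LOG_FLOOR = 1e-10

N_MFCC = 12
N_MEL = 40
N_FFT = 1024


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


@dataclass(frozen=True)
class MelFilterBank:
    """Triangular mel-spaced filters evaluated on rFFT bin frequencies."""

    weights: np.ndarray  # (n_channels, n_fft // 2 + 1)
    center_freqs_hz: np.ndarray
    n_fft: int
    sample_rate: int

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def build_mel_filterbank(
    n_channels: int = N_MEL,
    n_fft: int = N_FFT,
    sample_rate: int = 16000,
    f_low: float = 0.0,
    f_high: float | None = None,
) -> MelFilterBank:
    """Build ``n_channels`` triangular filters equally spaced on the mel scale.

    Filter edges are the mel-linear grid of ``n_channels + 2`` points
    between ``f_low`` and ``f_high`` (Nyquist by default); each filter
    rises linearly from its lower edge to its centre and falls to its
    upper edge, evaluated at the continuous bin frequencies.
    """
    nyq = sample_rate / 2.0
    if f_high is None:
        f_high = nyq
    if not (0.0 <= f_low < f_high <= nyq):
        raise ValueError(f"require 0 <= f_low < f_high <= Nyquist, got ({f_low}, {f_high})")
    mel_edges = np.linspace(hz_to_mel(f_low), hz_to_mel(f_high), n_channels + 2)
    hz_edges = np.asarray(mel_to_hz(mel_edges))
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    lower, center, upper = hz_edges[:-2], hz_edges[1:-1], hz_edges[2:]
    up = (bin_freqs[None, :] - lower[:, None]) / (center - lower)[:, None]
    down = (upper[:, None] - bin_freqs[None, :]) / (upper - center)[:, None]
    weights = np.maximum(0.0, np.minimum(up, down))
    return MelFilterBank(
        weights=weights,
        center_freqs_hz=center,
        n_fft=n_fft,
        sample_rate=sample_rate,
    )


def pre_emphasis(x: np.ndarray, coeff: float = 0.97) -> np.ndarray:
    """First-order high-pass emphasis: y[n] = x[n] - coeff * x[n-1]."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) == 0:
        return x.copy()
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - coeff * x[:-1]
    return y


def _windowed_spectra(frames: np.ndarray, n_fft: int) -> np.ndarray:
    """Hamming window each frame, zero-pad to n_fft, return rFFT magnitudes."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    window = np.hamming(frames.shape[1])
    return np.abs(rfft(frames * window, n=n_fft, axis=1))


def mfcc_frames(
    frames: np.ndarray,
    bank: MelFilterBank,
    n_coeff: int = N_MFCC,
    include_c0: bool = False,
    log_floor: float = LOG_FLOOR,
) -> np.ndarray:
    """Per-frame MFCC: power spectrum -> mel bank -> log -> orthonormal DCT-II.

    Returns ``n_coeff`` coefficients per frame; by default c1..c12 (the
    energy-like c0 is excluded, making the features invariant to a global
    gain).  ``include_c0=True`` switches to c0..c11.
    """
    mag = _windowed_spectra(frames, bank.n_fft)
    mel_power = (mag * mag) @ bank.weights.T
    log_mel = np.log(np.maximum(mel_power, log_floor))
    cepstra = dct(log_mel, type=2, norm="ortho", axis=1)
    if include_c0:
        return cepstra[:, :n_coeff]
    return cepstra[:, 1 : n_coeff + 1]


def mfmc_frames(
    frames: np.ndarray,
    bank: MelFilterBank,
    log_floor: float = LOG_FLOOR,
) -> np.ndarray:
    """Per-frame MFMC: amplitude spectrum -> mel bank -> log, no DCT."""
    mag = _windowed_spectra(frames, bank.n_fft)
    mel_amp = mag @ bank.weights.T
    return np.log(np.maximum(mel_amp, log_floor))


def _skewness(x: np.ndarray) -> np.ndarray:
    """Fisher-Pearson g1 per column; 0 where the variance vanishes."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    dev = x - mean
    m2 = np.mean(dev * dev, axis=0)
    m3 = np.mean(dev * dev * dev, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g1 = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
    return g1


def _five_stats(x: np.ndarray) -> dict[str, np.ndarray]:
    n, d = x.shape
    if n >= 2:
        sd = x.std(axis=0, ddof=1)
    else:
        sd = np.zeros(d)
    return {
        "mean": x.mean(axis=0),
        "sd": sd,
        "median": np.median(x, axis=0),
        "range": x.max(axis=0) - x.min(axis=0),
        "skewness": _skewness(x),
    }


def event_statistics(per_frame: np.ndarray) -> dict[str, np.ndarray]:
    """Pool a (n_frames, dim) trajectory into base and delta statistics.

    Returns a dict with keys ``mean, sd, median, range, skewness`` and the
    same names prefixed ``delta_``, each a length-``dim`` vector.  Deltas
    are first differences of consecutive frames; a single-frame event has
    zero spread statistics and all-zero delta statistics.
    """
    x = np.atleast_2d(np.asarray(per_frame, dtype=np.float64))
    if x.shape[0] == 0:
        raise ValueError("event contains no frames")
    stats = _five_stats(x)
    if x.shape[0] >= 2:
        delta_stats = _five_stats(np.diff(x, axis=0))
    else:
        delta_stats = {name: np.zeros(x.shape[1]) for name in STAT_ORDER}
    for name in STAT_ORDER:
        stats[f"delta_{name}"] = delta_stats[name]
    return stats


@dataclass(frozen=True)
class FeaturePatternSpec:
    """One of the 14 named feature patterns: base features x statistics."""

    pattern_id: str
    bases: tuple[str, ...]  # ("mfcc",), ("mfmc",) or ("mfcc", "mfmc")
    statistics: tuple[str, ...]
    include_deltas: bool

    @property
    def dimension(self) -> int:
        base_dims = {"mfcc": N_MFCC, "mfmc": N_MEL}
        per_stat = 2 if self.include_deltas else 1
        return sum(
            base_dims[b] * len(self.statistics) * per_stat for b in self.bases
        )


def _cumulative_patterns(base: str) -> dict[str, FeaturePatternSpec]:
    out = {}
    for i in range(1, 6):
        pid = f"{base.upper()}_P{i}"
        out[pid] = FeaturePatternSpec(pid, (base,), STAT_ORDER[:i], False)
    pid = f"{base.upper()}_P6"
    out[pid] = FeaturePatternSpec(pid, (base,), STAT_ORDER, True)
    return out


PATTERNS: dict[str, FeaturePatternSpec] = {
    **_cumulative_patterns("mfcc"),
    **_cumulative_patterns("mfmc"),
    "MIX_P1": FeaturePatternSpec("MIX_P1", ("mfcc", "mfmc"), STAT_ORDER, False),
    "MIX_P2": FeaturePatternSpec("MIX_P2", ("mfcc", "mfmc"), STAT_ORDER, True),
}


def _canonical_pattern_id(pattern_id: str) -> str:
    pid = pattern_id.upper().replace(" ", "_").replace("-", "_")
    if pid not in PATTERNS:
        raise KeyError(
            f"unknown feature pattern {pattern_id!r}; valid ids: {sorted(PATTERNS)}"
        )
    return pid


def assemble_pattern(
    pattern_id: str,
    mfcc_stats: dict[str, np.ndarray] | None = None,
    mfmc_stats: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Concatenate pooled statistics into the named pattern's vector.

    Order: MFCC block before MFMC block; within a block, base statistics
    in the canonical order (mean, sd, median, range, skewness) followed by
    the delta statistics in the same order; within a statistic, the
    coefficients in index order.
    """
    spec = PATTERNS[_canonical_pattern_id(pattern_id)]
    provided = {"mfcc": mfcc_stats, "mfmc": mfmc_stats}
    parts: list[np.ndarray] = []
    for base in spec.bases:
        stats = provided[base]
        if stats is None:
            raise ValueError(f"pattern {spec.pattern_id} requires {base} statistics")
        for name in spec.statistics:
            parts.append(np.asarray(stats[name], dtype=np.float64))
        if spec.include_deltas:
            for name in spec.statistics:
                parts.append(np.asarray(stats[f"delta_{name}"], dtype=np.float64))
    vec = np.concatenate(parts)
    if len(vec) != spec.dimension:
        raise AssertionError(
            f"assembled {len(vec)} dims for {spec.pattern_id}, expected {spec.dimension}"
        )
    return vec


def feature_names(pattern_id: str) -> list[str]:
    """Column names matching :func:`assemble_pattern`'s ordering."""
    spec = PATTERNS[_canonical_pattern_id(pattern_id)]
    dims = {"mfcc": N_MFCC, "mfmc": N_MEL}
    names: list[str] = []
    for base in spec.bases:
        stat_names = list(spec.statistics)
        if spec.include_deltas:
            stat_names += [f"delta_{s}" for s in spec.statistics]
        for stat in stat_names:
            names += [f"{base}{i + 1}_{stat}" for i in range(dims[base])]
    return names


def featurize_events(
    rec: AudioRecording,
    events: list[LoudEvent],
    pattern_id: str,
    frame_spec: FrameSpec | None = None,
    pre_emphasis_coeff: float = 0.97,
    bank: MelFilterBank | None = None,
    include_c0: bool = False,
) -> np.ndarray:
    """Compute one event feature vector per loud event.

    The whole recording is pre-emphasised once and framed on the global
    grid; an event's frames are the grid frames from its (padded)
    ``start_frame`` to ``end_frame``, clipped to the frames that fully fit
    in the signal.  Returns an ``(n_events, dim)`` matrix.
    """
    spec = PATTERNS[_canonical_pattern_id(pattern_id)]
    frame_spec = frame_spec or FrameSpec(sample_rate=rec.sample_rate)
    if bank is None:
        bank = build_mel_filterbank(sample_rate=rec.sample_rate)
    emphasised = pre_emphasis(rec.samples, pre_emphasis_coeff)
    frames = frame_signal(emphasised, frame_spec)
    if len(frames) == 0:
        raise ValueError("recording shorter than one frame")
    rows: list[np.ndarray] = []
    for ev in events:
        lo = max(0, ev.start_frame)
        hi = min(len(frames) - 1, ev.end_frame)
        if hi < lo:
            raise ValueError(
                f"event frames [{ev.start_frame}, {ev.end_frame}] fall outside the signal"
            )
        ev_frames = frames[lo : hi + 1]
        mfcc_stats = (
            event_statistics(mfcc_frames(ev_frames, bank, include_c0=include_c0))
            if "mfcc" in spec.bases
            else None
        )
        mfmc_stats = (
            event_statistics(mfmc_frames(ev_frames, bank))
            if "mfmc" in spec.bases
            else None
        )
        rows.append(assemble_pattern(spec.pattern_id, mfcc_stats, mfmc_stats))
    return np.vstack(rows) if rows else np.empty((0, spec.dimension))
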