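"""MFCC/MFMC frame features, statistic pooling, and the 14 patterns."""

import math

import numpy as np
import pytest

from swallowsound.event_detection import FrameSpec, LoudEvent
from swallowsound.features import (
    LOG_FLOOR,
    PATTERNS,
    assemble_pattern,
    build_mel_filterbank,
    event_statistics,
    feature_names,
    featurize_events,
    mfcc_frames,
    mfmc_frames,
    pre_emphasis,
)
from swallowsound.signal_io import AudioRecording

BANK = build_mel_filterbank()


def _tone_frame(freq_hz=1000.0, rate=16000, n=410, amp=0.4):
    return amp * np.sin(2 * np.pi * freq_hz * np.arange(n) / rate)[None, :]


class TestPreEmphasis:
    def test_zero_coeff_is_identity(self):
        x = np.random.default_rng(0).standard_normal(100)
        np.testing.assert_array_equal(pre_emphasis(x, coeff=0.0), x)

    def test_unit_impulse(self):
        out = pre_emphasis(np.array([1.0, 0.0, 0.0, 0.0]))
        np.testing.assert_allclose(out, [1.0, -0.97, 0.0, 0.0])

    def test_constant_signal(self):
        out = pre_emphasis(np.full(50, 2.0))
        assert out[0] == 2.0
        np.testing.assert_allclose(out[1:], 0.03 * 2.0, rtol=1e-12)


class TestMelFilterBank:
    def test_channel_count_and_shape(self):
        assert BANK.weights.shape == (40, 513)

    def test_filters_triangular_and_positive(self):
        for row in BANK.weights:
            assert row.max() > 0
            peak = int(np.argmax(row))
            nonzero = np.flatnonzero(row)
            # rises to the peak then falls
            assert np.all(np.diff(row[nonzero[0] : peak + 1]) >= -1e-12)
            assert np.all(np.diff(row[peak : nonzero[-1] + 1]) <= 1e-12)

    def test_center_frequencies_increasing(self):
        centers = BANK.center_freqs_hz
        assert np.all(np.diff(centers) > 0)
        assert centers[0] >= 0.0
        assert centers[-1] <= 8000.0

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            build_mel_filterbank(f_low=4000.0, f_high=1000.0)


def _oracle_mfcc_single_frame(x, n_mel=40, n_fft=1024, rate=16000):
    """Straight-line MFCC: explicit DFT, hand-built bank, explicit DCT."""
    n = len(x)
    window = np.array([0.54 - 0.46 * math.cos(2 * math.pi * k / (n - 1)) for k in range(n)])
    xw = np.zeros(n_fft)
    xw[:n] = x * window
    k = np.arange(n_fft // 2 + 1)
    spectrum = np.array(
        [sum(xw[t] * np.exp(-2j * math.pi * ki * t / n_fft) for t in range(n_fft)) for ki in k]
    )
    power = np.abs(spectrum) ** 2
    # hand-built mel bank
    def mel(f):
        return 2595.0 * math.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    edges = [imel(mel(0.0) + i * (mel(rate / 2) - mel(0.0)) / (n_mel + 1)) for i in range(n_mel + 2)]
    bin_freqs = k * rate / n_fft
    mel_energies = np.zeros(n_mel)
    for m in range(n_mel):
        lo, ce, hi = edges[m], edges[m + 1], edges[m + 2]
        for bi, f in enumerate(bin_freqs):
            if lo <= f <= ce:
                weight = (f - lo) / (ce - lo)
            elif ce < f <= hi:
                weight = (hi - f) / (hi - ce)
            else:
                weight = 0.0
            mel_energies[m] += weight * power[bi]
    logmel = np.log(np.maximum(mel_energies, LOG_FLOOR))
    coeffs = np.zeros(13)
    for i in range(13):
        scale = math.sqrt(1.0 / n_mel) if i == 0 else math.sqrt(2.0 / n_mel)
        coeffs[i] = scale * sum(
            logmel[j] * math.cos(math.pi * i * (2 * j + 1) / (2 * n_mel)) for j in range(n_mel)
        )
    return coeffs[1:13]


class TestMfcc:
    def test_dimension(self):
        out = mfcc_frames(np.random.default_rng(1).standard_normal((3, 410)), BANK)
        assert out.shape == (3, 12)

    def test_gain_invariance(self):
        frames = _tone_frame()
        np.testing.assert_allclose(
            mfcc_frames(3.0 * frames, BANK), mfcc_frames(frames, BANK), atol=1e-9
        )

    def test_matches_straight_line_oracle(self):
        frame = _tone_frame()[0]
        fast = mfcc_frames(frame[None, :], BANK)[0]
        slow = _oracle_mfcc_single_frame(frame)
        np.testing.assert_allclose(fast, slow, atol=1e-6)


class TestMfmc:
    def test_dimension(self):
        out = mfmc_frames(np.random.default_rng(2).standard_normal((5, 410)), BANK)
        assert out.shape == (5, 40)

    def test_gain_shift_log_a(self):
        frames = _tone_frame()
        shift = mfmc_frames(3.0 * frames, BANK) - mfmc_frames(frames, BANK)
        np.testing.assert_allclose(shift, math.log(3.0), atol=1e-9)

    def test_zero_frame_hits_floor(self):
        out = mfmc_frames(np.zeros((1, 410)), BANK)
        np.testing.assert_allclose(out, math.log(LOG_FLOOR))


class TestEventStatistics:
    def test_hand_computed_values(self):
        x = np.array([[1.0], [2.0], [4.0]])
        stats = event_statistics(x)
        assert stats["mean"][0] == pytest.approx(7.0 / 3.0)
        assert stats["sd"][0] == pytest.approx(1.527525, abs=1e-5)
        assert stats["median"][0] == 2.0
        assert stats["range"][0] == 3.0
        assert stats["skewness"][0] == pytest.approx(0.381802, abs=1e-5)
        assert stats["delta_mean"][0] == pytest.approx(1.5)
        assert stats["delta_range"][0] == pytest.approx(1.0)

    def test_constant_frames_degenerate_spread(self):
        stats = event_statistics(np.full((5, 3), 2.0))
        for name in ("sd", "range", "skewness"):
            np.testing.assert_array_equal(stats[name], 0.0)

    def test_single_frame_event(self):
        stats = event_statistics(np.array([[1.0, -2.0]]))
        np.testing.assert_array_equal(stats["mean"], [1.0, -2.0])
        for name in ("sd", "range", "skewness"):
            np.testing.assert_array_equal(stats[name], 0.0)
        for name in ("delta_mean", "delta_sd", "delta_median", "delta_range", "delta_skewness"):
            np.testing.assert_array_equal(stats[name], 0.0)

    def test_empty_event_rejected(self):
        with pytest.raises(ValueError):
            event_statistics(np.empty((0, 12)))


EXPECTED_DIMS = {
    "MFCC_P1": 12, "MFCC_P2": 24, "MFCC_P3": 36, "MFCC_P4": 48,
    "MFCC_P5": 60, "MFCC_P6": 120,
    "MFMC_P1": 40, "MFMC_P2": 80, "MFMC_P3": 120, "MFMC_P4": 160,
    "MFMC_P5": 200, "MFMC_P6": 400,
    "MIX_P1": 260, "MIX_P2": 520,
}


class TestPatterns:
    @pytest.mark.parametrize("pattern_id,dim", sorted(EXPECTED_DIMS.items()))
    def test_assembled_dimensions(self, pattern_id, dim):
        rng = np.random.default_rng(3)
        mfcc_stats = event_statistics(rng.standard_normal((6, 12)))
        mfmc_stats = event_statistics(rng.standard_normal((6, 40)))
        vec = assemble_pattern(pattern_id, mfcc_stats, mfmc_stats)
        assert len(vec) == dim
        assert PATTERNS[pattern_id].dimension == dim
        assert len(feature_names(pattern_id)) == dim

    def test_unknown_pattern_rejected(self):
        with pytest.raises(KeyError):
            assemble_pattern("MFCC_P9", None, None)

    def test_missing_base_rejected(self):
        rng = np.random.default_rng(4)
        stats = event_statistics(rng.standard_normal((4, 12)))
        with pytest.raises(ValueError):
            assemble_pattern("MIX_P1", mfcc_stats=stats, mfmc_stats=None)

    def test_block_ordering(self):
        # MFCC block precedes MFMC; base statistics precede deltas
        names = feature_names("MIX_P2")
        assert names[0] == "mfcc1_mean"
        assert names.index("mfcc1_delta_mean") == 60
        assert names.index("mfmc1_mean") == 120
        assert names.index("mfmc1_delta_mean") == 320


class TestFeaturizeEvents:
    def _recording_and_event(self, gain=1.0):
        rng = np.random.default_rng(5)
        x = 0.1 * rng.standard_normal(16000)
        x[4000:8000] += 0.4 * np.sin(2 * np.pi * 1200 * np.arange(4000) / 16000)
        rec = AudioRecording(gain * x, 16000)
        event = LoudEvent.from_frames(20, 60, FrameSpec())
        return rec, [event]

    def test_gain_effects_on_event_features(self):
        """MFCC stats are gain-invariant; MFMC means shift by ln(a) while
        spread/delta statistics are gain-invariant."""
        rec1, events = self._recording_and_event(1.0)
        rec2, _ = self._recording_and_event(2.5)
        f_mfcc_1 = featurize_events(rec1, events, "MFCC_P6")
        f_mfcc_2 = featurize_events(rec2, events, "MFCC_P6")
        np.testing.assert_allclose(f_mfcc_1, f_mfcc_2, atol=1e-8)

        f1 = featurize_events(rec1, events, "MFMC_P6")
        f2 = featurize_events(rec2, events, "MFMC_P6")
        # mean block shifts by ln a
        np.testing.assert_allclose(f2[0, :40] - f1[0, :40], math.log(2.5), atol=1e-8)
        # sd / median-shift excluded: median also shifts; sd, range, skewness do not
        np.testing.assert_allclose(f2[0, 40:80], f1[0, 40:80], atol=1e-8)  # sd
        np.testing.assert_allclose(f2[0, 120:160], f1[0, 120:160], atol=1e-8)  # range
        np.testing.assert_allclose(f2[0, 160:200], f1[0, 160:200], atol=1e-8)  # skewness
        # all delta statistics are differences -> gain-invariant
        np.testing.assert_allclose(f2[0, 200:], f1[0, 200:], atol=1e-8)

    def test_deterministic(self):
        rec, events = self._recording_and_event()
        a = featurize_events(rec, events, "MIX_P2")
        b = featurize_events(rec, events, "MIX_P2")
        np.testing.assert_array_equal(a, b)

    def test_event_outside_signal_rejected(self):
        rec, _ = self._recording_and_event()
        bad = [LoudEvent.from_frames(5000, 5100, FrameSpec())]
        with pytest.raises(ValueError):
            featurize_events(rec, bad, "MFCC_P1")
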