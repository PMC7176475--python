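import numpy as np
import pytest

from navakit import (
    DegenerateSignal,
    TitrationRecording,
    ValidationError,
    classify_frames,
    extract_inspirations,
    frame_features,
    lowpass_ma,
    paw_peaks,
)
from navakit.breath_detection import LABEL_EXPIRATION, LABEL_INSPIRATION, BreathInterval


class TestLowpassMa:
    def test_constant_passes_through(self):
        out = lowpass_ma(np.full(200, 3.5), 40)
        np.testing.assert_allclose(out, 3.5)

    def test_impulse_response(self):
        x = np.zeros(300)
        x[100] = 1.0
        out = lowpass_ma(x, 40)
        np.testing.assert_allclose(out[100:140], 1 / 40)
        assert np.all(out[140:] == 0) and np.all(out[:100] == 0)

    def test_nonnegative_input_nonnegative_output(self):
        rng = np.random.default_rng(0)
        out = lowpass_ma(np.abs(rng.normal(0, 1, 500)), 40)
        assert np.all(out >= 0)

    def test_sinusoid_attenuation_matches_closed_form(self):
        fs, order, f = 62.5, 40, 10.0
        n = np.arange(8000)
        out = lowpass_ma(np.sin(2 * np.pi * f * n / fs), order)[2000:]
        design = np.column_stack([
            np.sin(2 * np.pi * f * n[2000:] / fs),
            np.cos(2 * np.pi * f * n[2000:] / fs),
        ])
        coeffs, *_ = np.linalg.lstsq(design, out, rcond=None)
        measured = np.hypot(*coeffs)
        predicted = abs(
            np.sin(np.pi * f * order / fs) / (order * np.sin(np.pi * f / fs))
        )
        assert measured == pytest.approx(predicted, rel=0.02)

    def test_signal_shorter_than_order(self):
        with pytest.raises(ValidationError):
            lowpass_ma(np.ones(10), 40)


class TestFrameFeatures:
    def test_constant_two(self):
        frames = frame_features(np.full(150, 2.0), 15)
        assert all(f.e == pytest.approx(np.log(4)) for f in frames)
        assert frames[0].de == 0.0
        assert all(f.de == pytest.approx(0.0) for f in frames[1:])

    def test_all_zero_floored(self):
        frames = frame_features(np.zeros(150), 15, floor=1e-12)
        assert all(f.e == pytest.approx(np.log(1e-12)) for f in frames)

    def test_frame_count_3000_over_15(self):
        assert len(frame_features(np.random.default_rng(0).normal(size=3000), 15)) == 200

    def test_trailing_partial_frame_discarded(self):
        assert len(frame_features(np.ones(44), 15)) == 2


def burst_train(rng, n_sec=300, fs=62.5, burst_s=1.0, cycle_s=3.0, amp=10.0,
                baseline=0.3, noise=0.05):
    n = int(n_sec * fs)
    x = np.full(n, baseline)
    truth = np.zeros(n, bool)
    t = 0.0
    while (s := int(t * fs)) + int(burst_s * fs) < n:
        ni = int(burst_s * fs)
        x[s: s + ni] += amp * np.sin(np.pi * (np.arange(ni) + 0.5) / ni)
        truth[s: s + ni] = True
        t += cycle_s
    return np.maximum(x + rng.normal(0, noise, n), 0), truth


class TestClassifyFrames:
    def test_burst_train_detection(self, cfg):
        rng = np.random.default_rng(3)
        x, truth = burst_train(rng)
        labels, gmm = classify_frames(frame_features(lowpass_ma(x, 40), 15), cfg)
        n_frames = len(labels)
        truth_frames = truth[: n_frames * 15].reshape(n_frames, 15).mean(1) >= 0.5
        pred = labels == LABEL_INSPIRATION
        recall = (pred & truth_frames).sum() / truth_frames.sum()
        assert recall >= 0.85  # edges blur by ~1 frame (causal MA + framing)
        # every planted burst overlaps a detected interval, and the breath
        # count is exact on this regular train
        detected = extract_inspirations(labels, 15)
        burst_starts = np.nonzero(
            np.diff(np.concatenate(([0], truth.astype(int)))) == 1)[0]
        for s in burst_starts:
            assert any(d.s <= s + 32 and d.e > s for d in detected)
        assert len(detected) == len(burst_starts)

    def test_breath_count_accuracy(self, cfg, default_session):
        rec, truth = default_session
        labels, _ = classify_frames(frame_features(lowpass_ma(rec.eadi, 40), 15), cfg)
        detected = extract_inspirations(labels, 15)
        n_true = len(truth.neural_intervals)
        assert abs(len(detected) - n_true) <= 0.1 * n_true

    def test_constant_signal_degenerate(self, cfg):
        with pytest.raises(DegenerateSignal):
            classify_frames(frame_features(np.full(3000, 2.0), 15), cfg)


class TestExtractInspirations:
    def test_single_run(self):
        labels = [LABEL_EXPIRATION, LABEL_INSPIRATION, LABEL_INSPIRATION,
                  LABEL_EXPIRATION]
        (iv,) = extract_inspirations(labels, 15)
        assert (iv.s, iv.e, iv.b, iv.kind) == (15, 45, 0, "neural")

    def test_all_expiration_empty(self):
        assert extract_inspirations([LABEL_EXPIRATION] * 5, 15) == []

    def test_alternating_single_frame_intervals(self):
        labels = [LABEL_INSPIRATION, LABEL_EXPIRATION] * 4
        ivs = extract_inspirations(labels, 15)
        assert len(ivs) == 4
        assert all(iv.length == 15 for iv in ivs)
        assert [iv.b for iv in ivs] == [0, 1, 2, 3]


class TestPawPeaks:
    @staticmethod
    def _rec(nava, eadi):
        n = len(eadi)
        return TitrationRecording(62.5, np.full(n, nava) if np.isscalar(nava)
                                  else nava, eadi, np.zeros(n))

    def test_product_and_argmax(self):
        eadi = np.ones(200)
        eadi[100] = 8.0
        rec = self._rec(2.0, eadi)
        idx, val = paw_peaks(rec, [BreathInterval("neural", 0, 80, 120)])
        assert idx[0] == 100 and val[0] == pytest.approx(16.0)

    def test_two_breaths_increasing_indices(self):
        eadi = np.ones(300)
        eadi[50], eadi[220] = 5.0, 6.0
        rec = self._rec(1.0, eadi)
        idx, _ = paw_peaks(rec, [BreathInterval("neural", 0, 30, 90),
                                 BreathInterval("neural", 1, 200, 260)])
        assert list(idx) == [50, 220]

    def test_flat_paw_ties_to_earliest(self):
        rec = self._rec(2.0, np.ones(100))
        idx, _ = paw_peaks(rec, [BreathInterval("neural", 0, 20, 60)])
        assert idx[0] == 20

    def test_invariant_to_expiration_artifacts(self):
        eadi = np.ones(300)
        eadi[150] = 7.0
        rec_clean = self._rec(2.0, eadi.copy())
        eadi[10] = 50.0  # artifact outside the inspiration interval
        rec_dirty = self._rec(2.0, eadi)
        iv = [BreathInterval("neural", 0, 120, 180)]
        np.testing.assert_array_equal(paw_peaks(rec_clean, iv)[1],
                                      paw_peaks(rec_dirty, iv)[1])
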