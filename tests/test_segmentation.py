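"""ROI-SSE segmentation: envelope, SSE profile, detection, ECG reference."""

import numpy as np
import pytest

from s2cavd.pcg_synth import SynthProtocol, SyntheticSubject, synthesize_paired_ecg, synthesize_recording
from s2cavd.segmentation import (
    CycleSegmentation,
    SSEProfile,
    compare_segmentations,
    detect_cycle_starts,
    ecg_segment,
    locate_respiratory_artifact,
    peak_normalize,
    rms_envelope,
    segment_recording,
    sse_profile,
    validate_roi,
)
from s2cavd.workbench import pick_roi


def brute_force_sse(roi: np.ndarray, rec: np.ndarray) -> np.ndarray:
    """Independent double-loop oracle for the SSE profile."""
    out = np.empty(len(rec) - len(roi) + 1)
    for k in range(len(out)):
        acc = 0.0
        for i in range(len(roi)):
            d = roi[i] - rec[k + i]
            acc += d * d
        out[k] = acc
    return out


class TestRmsEnvelope:
    def test_constant_signal(self):
        env = rms_envelope(np.full(1000, -3.0), 5.0, 10_000.0)
        assert env == pytest.approx(3.0)

    def test_sine_interior_is_a_over_sqrt2(self):
        fs, amp = 10_000.0, 2.0
        t = np.arange(5000) / fs
        env = rms_envelope(amp * np.sin(2 * np.pi * 100.0 * t), 50.0, fs)
        interior = env[1000:-1000]
        assert np.allclose(interior, amp / np.sqrt(2), rtol=0.01)

    def test_zeros_and_errors(self):
        assert np.all(rms_envelope(np.zeros(100), 2.0, 10_000.0) == 0)
        with pytest.raises(ValueError, match="longer than signal"):
            rms_envelope(np.ones(10), 100.0, 10_000.0)
        with pytest.raises(ValueError, match="spans no samples"):
            rms_envelope(np.ones(10), 0.001, 1000.0)


class TestSSEProfile:
    def test_self_match_is_exact_zero(self):
        rng = np.random.default_rng(0)
        roi = rng.random(200)
        prof = sse_profile(roi, roi)
        assert prof.values.shape == (1,)
        assert prof.values[0] == 0.0

    def test_tiled_roi_zeros_at_multiples(self):
        rng = np.random.default_rng(1)
        roi = rng.random(50)
        rec = np.tile(roi, 5)
        prof = sse_profile(roi, rec)
        zero_offsets = np.nonzero(prof.values == 0.0)[0]
        assert list(zero_offsets) == [0, 50, 100, 150, 200]

    def test_fft_path_matches_double_loop(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            rec = rng.standard_normal(600)
            roi = rec[100:180].copy()
            expected = brute_force_sse(roi, rec)
            got = sse_profile(roi, rec, method="fft").values
            assert np.max(np.abs(got - expected)) <= 1e-9 * np.max(expected)

    def test_roi_longer_than_recording_rejected(self):
        with pytest.raises(ValueError, match="longer than recording"):
            sse_profile(np.ones(10), np.ones(5))

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(3)
        rec = rng.standard_normal(500)
        prof = sse_profile(rec[50:120], rec, method="fft")
        assert np.all(prof.values >= 0)


class TestDetectCycleStarts:
    def _profile_with_zeros(self, L=100, n=3):
        vals = np.full(n * L + 1, 100.0)
        for k in range(n):
            vals[k * L] = 0.0
        return SSEProfile(values=vals, roi_length=L)

    def test_zeros_below_threshold_found(self):
        seg = detect_cycle_starts(self._profile_with_zeros(), threshold=10.0)
        assert list(seg.cycle_starts) == [0, 100, 200]

    def test_uniform_profile_gives_empty_with_warning(self):
        prof = SSEProfile(values=np.full(500, 100.0), roi_length=100)
        seg = detect_cycle_starts(prof, threshold=10.0)
        assert seg.n_cycles == 0
        assert "warning" in seg.status

    def test_min_separation_suppresses_duplicates(self):
        vals = np.full(300, 100.0)
        vals[50], vals[60] = 0.5, 1.0  # two nearby minima: keep the lower
        seg = detect_cycle_starts(SSEProfile(values=vals, roi_length=100), threshold=10.0)
        assert list(seg.cycle_starts) == [50]

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError, match="threshold"):
            detect_cycle_starts(SSEProfile(values=np.ones(10), roi_length=5), threshold=0.0)


class TestArtifact:
    def test_unique_max_and_tie_break(self):
        vals = np.array([1.0, 5.0, 3.0])
        assert locate_respiratory_artifact(SSEProfile(values=vals, roi_length=1)) == 1
        tie = np.array([1.0, 7.0, 7.0, 2.0])
        assert locate_respiratory_artifact(SSEProfile(values=tie, roi_length=1)) == 1

    def test_planted_artifact_located_within_span(self, compact_protocol):
        subj = SyntheticSubject("a01", "M", "Control")
        rec, truth = synthesize_recording(compact_protocol, subj)
        roi = pick_roi(truth, rec)
        _, prof = segment_recording(rec.samples, rec.sampling_rate_hz, roi)
        loc = locate_respiratory_artifact(prof)
        (a0, a1), = truth.artifact_spans
        # the ROI overlapping the artifact starts up to one ROI length earlier
        assert a0 - roi.length <= loc <= a1


class TestValidateRoi:
    def test_synthetic_cycle_accepted(self, healthy_recording):
        rec, truth = healthy_recording
        roi = pick_roi(truth, rec)
        assert roi.systole_ms < roi.diastole_ms

    def test_reversed_cycle_rejected(self):
        fs = 10_000.0
        t = np.arange(int(0.15 * fs)) / fs
        sig = np.zeros_like(t)
        # two bursts with the long gap first: "systole" >= "diastole"
        for onset, amp in ((0.0, 1.0), (0.1, 0.8)):
            idx = (t >= onset) & (t < onset + 0.012)
            sig[idx] += amp * np.sin(2 * np.pi * 200 * t[idx])
        with pytest.raises(ValueError, match="systole"):
            validate_roi(sig, 0, len(sig), fs)

    def test_single_burst_rejected(self):
        fs = 10_000.0
        t = np.arange(int(0.1 * fs)) / fs
        sig = np.sin(2 * np.pi * 200 * t) * np.exp(-t / 0.01)
        with pytest.raises(ValueError, match="two envelope bursts"):
            validate_roi(sig, 0, len(sig), fs)


class TestEcgSegment:
    def test_planted_peak_count_and_timing(self, compact_protocol):
        subj = SyntheticSubject("e01", "F", "Control")
        _, truth = synthesize_recording(compact_protocol, subj)
        ecg = synthesize_paired_ecg(truth, 24_414.0, seed=5)
        seg = ecg_segment(ecg, 24_414.0, pcg_rate_hz=truth.sampling_rate_hz)
        assert seg.n_cycles == len(truth.r_peaks)
        err_ms = [
            np.min(np.abs(seg.cycle_starts - p)) / truth.sampling_rate_hz * 1e3
            for p in truth.r_peaks
        ]
        assert max(err_ms) <= 1.0

    def test_flat_trace_empty(self):
        seg = ecg_segment(np.zeros(1000), 1000.0)
        assert seg.n_cycles == 0


class TestCompare:
    def _seg(self, starts, rate=1000.0):
        starts = np.asarray(starts, dtype=np.int64)
        return CycleSegmentation(
            cycle_starts=starts,
            cycle_durations_ms=np.diff(starts) / rate * 1e3,
            artifact_location=None,
            method="ROI-SSE",
            sampling_rate_hz=rate,
        )

    def test_identical_segmentations_zero_error(self):
        a = self._seg([0, 150, 300, 450])
        cmp = compare_segmentations(a, a)
        assert cmp.abs_error_duration_ms == 0.0
        assert cmp.abs_error_count == 0.0

    def test_duration_error_arithmetic(self):
        a = self._seg(np.arange(11) * 147)  # 10 cycles of 147 ms at 1 kHz
        b = self._seg(np.arange(11) * 150)
        cmp = compare_segmentations(a, b)
        assert cmp.abs_error_duration_ms == pytest.approx(3.0)
        assert cmp.abs_error_count == 0

    def test_empty_rejected(self):
        a = self._seg([0, 100])
        b = self._seg([])
        with pytest.raises(ValueError, match="empty"):
            compare_segmentations(a, b)


def test_segmentation_translation_equivariance(compact_protocol):
    """Shifting the recording shifts every detected start by the same lag."""
    subj = SyntheticSubject("t02", "M", "Control")
    rec, truth = synthesize_recording(compact_protocol, subj)
    roi = pick_roi(truth, rec)
    seg0, _ = segment_recording(rec.samples, rec.sampling_rate_hz, roi)
    shift = 500
    shifted = np.concatenate((np.zeros(shift), rec.samples))
    roi_shifted = validate_roi(
        shifted, roi.start_index + shift, roi.end_index + shift, rec.sampling_rate_hz
    )
    seg1, _ = segment_recording(shifted, rec.sampling_rate_hz, roi_shifted)
    common = min(seg0.n_cycles, seg1.n_cycles)
    assert common >= seg0.n_cycles - 1  # one start may fall off the valid range
    diffs = seg1.cycle_starts[:common] - seg0.cycle_starts[:common]
    assert np.all(np.abs(diffs - shift) <= 1)
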