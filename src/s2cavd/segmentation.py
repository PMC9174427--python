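"""Cardiac-cycle segmentation of phonocardiograms.

The primary method is ROI-SSE template matching: the operator selects a
region of interest (ROI) spanning exactly one cardiac cycle, and the
sum-of-squares error (SSE) between the RMS envelope of the ROI and the RMS
envelope of the whole recording is evaluated at every admissible alignment
offset.  Offsets where the SSE is lowest (below a threshold, "closest to
zero") mark the starting points of cardiac cycles; the offset of highest SSE
marks a respiratory movement artifact.

An ECG-based reference segmentation (R-peak picking with a refractory
period) and comparison metrics are provided to verify ROI-SSE output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage, signal as sps

#: Default SSE acceptance threshold on peak-normalized recordings.
DEFAULT_SSE_THRESHOLD = 10.0
#: Default RMS-envelope window: shorter than an S1/S2 burst, longer than the
#: sound's carrier period.
DEFAULT_WINDOW_MS = 5.0
#: Minimum spacing between accepted cycle starts, as a fraction of ROI length.
DEFAULT_MIN_SEPARATION = 0.6


@dataclass
class ROITemplate:
    """One manually selected cardiac cycle used as the matching template."""

    start_index: int
    end_index: int
    envelope: np.ndarray
    systole_ms: float
    diastole_ms: float

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("ROI end_index must exceed start_index")

    @property
    def length(self) -> int:
        return self.end_index - self.start_index


@dataclass
class SSEProfile:
    """SSE between the ROI envelope and the recording envelope per offset."""

    values: np.ndarray
    roi_length: int


@dataclass
class CycleSegmentation:
    """Detected cycle starts (sample indices) and derived durations."""

    cycle_starts: np.ndarray
    cycle_durations_ms: np.ndarray
    artifact_location: Optional[int]
    method: str
    sampling_rate_hz: float
    status: str = "ok"

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_starts)

    @property
    def mean_duration_ms(self) -> float:
        return float(np.mean(self.cycle_durations_ms)) if len(self.cycle_durations_ms) else float("nan")


@dataclass
class SegmentationComparison:
    """Agreement metrics between two segmentations of one recording.

    Both the raw cycle-count difference and its normalized form are
    reported; neither is privileged.
    """

    n_cycles_a: int
    n_cycles_b: int
    mean_duration_a_ms: float
    mean_duration_b_ms: float
    abs_error_duration_ms: float
    abs_error_count: float
    abs_error_count_normalized: float


def peak_normalize(samples: np.ndarray) -> np.ndarray:
    """Scale a signal to unit maximum absolute amplitude."""
    samples = np.asarray(samples, dtype=float)
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak == 0:
        return samples.copy()
    return samples / peak


def rms_envelope(samples: np.ndarray, window_ms: float, rate_hz: float) -> np.ndarray:
    """Root-mean-squared envelope over a moving window (same length as input)."""
    samples = np.asarray(samples, dtype=float)
    win = int(round(window_ms * 1e-3 * rate_hz))
    if win < 1:
        raise ValueError(f"window of {window_ms} ms spans no samples at {rate_hz} Hz")
    if win > len(samples):
        raise ValueError(f"window ({win} samples) longer than signal ({len(samples)})")
    mean_sq = ndimage.uniform_filter1d(samples**2, size=win, mode="nearest")
    return np.sqrt(np.clip(mean_sq, 0.0, None))


def sse_profile(
    roi_envelope: np.ndarray, recording_envelope: np.ndarray, method: str = "auto"
) -> SSEProfile:
    """Slide the ROI envelope along the recording envelope, accumulating SSE.

    ``values[k] = sum_i (roi[i] - rec[k + i])**2`` for every offset ``k``
    where the ROI fits entirely inside the recording (no padding: offsets
    that would overrun the recording are excluded).

    ``method='direct'`` subtracts windows explicitly (exact, memory-heavy);
    ``method='fft'`` uses the expansion ``sum roi^2 - 2 conv + windowed sum
    rec^2`` with overlap-add convolution; ``'auto'`` picks by problem size.
    """
    roi = np.asarray(roi_envelope, dtype=float)
    rec = np.asarray(recording_envelope, dtype=float)
    L, N = len(roi), len(rec)
    if L == 0:
        raise ValueError("empty ROI envelope")
    if L > N:
        raise ValueError(f"ROI ({L} samples) longer than recording ({N})")
    n_off = N - L + 1
    if method == "auto":
        method = "direct" if n_off * L <= 20_000_000 else "fft"
    if method == "direct":
        windows = np.lib.stride_tricks.sliding_window_view(rec, L)
        values = np.einsum("ij,ij->i", windows - roi, windows - roi)
    elif method == "fft":
        roi_energy = float(np.dot(roi, roi))
        cross = sps.oaconvolve(rec, roi[::-1], mode="valid")
        csum = np.concatenate(([0.0], np.cumsum(rec**2)))
        win_energy = csum[L:] - csum[:-L]
        values = np.clip(roi_energy - 2.0 * cross + win_energy, 0.0, None)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SSEProfile(values=values, roi_length=L)


def _local_minima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local minima, endpoints included."""
    padded = np.concatenate(([np.inf], values, [np.inf]))
    core = padded[1:-1]
    return np.nonzero((core < padded[:-2]) & (core <= padded[2:]))[0]


def detect_cycle_starts(
    profile: SSEProfile,
    threshold: float = DEFAULT_SSE_THRESHOLD,
    min_separation_fraction: float = DEFAULT_MIN_SEPARATION,
    rate_hz: float = 100_000.0,
    relative: bool = False,
) -> CycleSegmentation:
    """Mark cycle starts at low-SSE local minima of the profile.

    "Closest to zero" is operationalized as: local minima below the
    threshold, accepted greedily in increasing-SSE order subject to a
    pairwise separation of at least ``min_separation_fraction`` times the
    ROI length (preventing duplicate detections within one cycle).  With
    ``relative=True`` the threshold is a fraction of the profile median,
    making the cut scale-free.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = profile.values
    thr = threshold * float(np.median(values)) if relative else threshold
    minima = _local_minima(values)
    minima = minima[values[minima] < thr]
    order = np.lexsort((minima, values[minima]))
    min_sep = int(round(min_separation_fraction * profile.roi_length))
    accepted: List[int] = []
    for idx in minima[order]:
        if all(abs(int(idx) - a) >= min_sep for a in accepted):
            accepted.append(int(idx))
    starts = np.asarray(sorted(accepted), dtype=np.int64)
    durations = np.diff(starts) / rate_hz * 1e3
    status = "ok" if len(starts) else "warning: no SSE minima below threshold"
    artifact = locate_respiratory_artifact(profile) if len(values) else None
    return CycleSegmentation(
        cycle_starts=starts,
        cycle_durations_ms=durations,
        artifact_location=artifact,
        method="ROI-SSE",
        sampling_rate_hz=rate_hz,
        status=status,
    )


def locate_respiratory_artifact(profile: SSEProfile) -> int:
    """Offset of highest SSE = location of a respiratory movement artifact.

    Ties break to the smallest offset.
    """
    if len(profile.values) == 0:
        raise ValueError("empty SSE profile")
    return int(np.argmax(profile.values))


def _find_bursts(envelope: np.ndarray, threshold_fraction: float = 0.25) -> List[Tuple[int, int]]:
    """Maximal runs where the envelope exceeds a fraction of its maximum."""
    if envelope.size == 0:
        return []
    mask = envelope > threshold_fraction * np.max(envelope)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def validate_roi(
    recording: np.ndarray,
    start: int,
    end: int,
    rate_hz: float,
    window_ms: float = DEFAULT_WINDOW_MS,
    burst_threshold_fraction: float = 0.25,
) -> ROITemplate:
    """Check a candidate ROI and build the matching template.

    The ROI must contain two resolvable envelope bursts (S1 then S2); the
    systolic interval (first burst onset to second burst onset) must be
    shorter than the remaining diastolic interval, which is the validity
    rule for a cycle where systole precedes diastole.  The recording is
    peak-normalized before envelope computation.
    """
    samples = np.asarray(recording, dtype=float)
    if not (0 <= start < end <= len(samples)):
        raise ValueError(f"ROI indices [{start}, {end}) out of range for {len(samples)} samples")
    env = rms_envelope(peak_normalize(samples), window_ms, rate_hz)
    roi_env = env[start:end]
    bursts = _find_bursts(roi_env, burst_threshold_fraction)
    if len(bursts) < 2:
        raise ValueError(
            f"ROI rejected: expected two envelope bursts (S1, S2), found {len(bursts)}"
        )
    systole_samples = bursts[1][0] - bursts[0][0]
    diastole_samples = (end - start) - systole_samples
    systole_ms = systole_samples / rate_hz * 1e3
    diastole_ms = diastole_samples / rate_hz * 1e3
    if systole_ms >= diastole_ms:
        raise ValueError(
            "ROI rejected: systole ({:.1f} ms) not shorter than diastole ({:.1f} ms); "
            "select a cycle where systole precedes diastole".format(systole_ms, diastole_ms)
        )
    return ROITemplate(
        start_index=start,
        end_index=end,
        envelope=roi_env,
        systole_ms=systole_ms,
        diastole_ms=diastole_ms,
    )


def segment_recording(
    samples: np.ndarray,
    rate_hz: float,
    roi: ROITemplate,
    threshold: float = DEFAULT_SSE_THRESHOLD,
    window_ms: float = DEFAULT_WINDOW_MS,
    min_separation_fraction: float = DEFAULT_MIN_SEPARATION,
    relative: bool = False,
) -> Tuple[CycleSegmentation, SSEProfile]:
    """Full ROI-SSE pass: normalize, envelope, SSE profile, start detection."""
    env = rms_envelope(peak_normalize(np.asarray(samples, dtype=float)), window_ms, rate_hz)
    profile = sse_profile(roi.envelope, env)
    seg = detect_cycle_starts(
        profile,
        threshold=threshold,
        min_separation_fraction=min_separation_fraction,
        rate_hz=rate_hz,
        relative=relative,
    )
    return seg, profile


def ecg_segment(
    ecg: np.ndarray,
    ecg_rate_hz: float,
    pcg_rate_hz: Optional[float] = None,
    refractory_ms: float = 50.0,
) -> CycleSegmentation:
    """Reference segmentation from a paired single-lead ECG.

    R-peaks are picked where the trace and its slope exceed robust
    thresholds, with a refractory period suppressing double detections;
    each R-peak marks the start of systole.  Cycle starts are converted to
    the PCG timebase by nearest-sample rounding (ties round down) when
    ``pcg_rate_hz`` is given.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size == 0:
        raise ValueError("empty ECG trace")
    spread = float(np.std(ecg))
    if spread == 0:
        peaks = np.array([], dtype=np.int64)
    else:
        height = float(np.mean(ecg)) + 4.0 * spread
        distance = max(1, int(round(refractory_ms * 1e-3 * ecg_rate_hz)))
        peaks, _ = sps.find_peaks(ecg, height=height, distance=distance)
    if pcg_rate_hz is not None and pcg_rate_hz != ecg_rate_hz:
        ratio = pcg_rate_hz / ecg_rate_hz
        starts = np.ceil(peaks * ratio - 0.5).astype(np.int64)  # half-ties down
        out_rate = pcg_rate_hz
    else:
        starts = peaks.astype(np.int64)
        out_rate = ecg_rate_hz
    durations = np.diff(starts) / out_rate * 1e3
    return CycleSegmentation(
        cycle_starts=starts,
        cycle_durations_ms=durations,
        artifact_location=None,
        method="ECG",
        sampling_rate_hz=out_rate,
        status="ok" if len(starts) else "warning: no R-peaks found",
    )


def compare_segmentations(a: CycleSegmentation, b: CycleSegmentation) -> SegmentationComparison:
    """Cycle-count and mean-duration agreement between two segmentations."""
    if a.n_cycles == 0 or b.n_cycles == 0:
        raise ValueError("cannot compare an empty segmentation")
    dur_a, dur_b = a.mean_duration_ms, b.mean_duration_ms
    count_err = abs(a.n_cycles - b.n_cycles)
    return SegmentationComparison(
        n_cycles_a=a.n_cycles,
        n_cycles_b=b.n_cycles,
        mean_duration_a_ms=dur_a,
        mean_duration_b_ms=dur_b,
        abs_error_duration_ms=abs(dur_a - dur_b),
        abs_error_count=float(count_err),
        abs_error_count_normalized=count_err / max(a.n_cycles, b.n_cycles),
    )
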