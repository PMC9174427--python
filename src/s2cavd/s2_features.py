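"""S2 sound isolation, preprocessing, and PCA feature space.

After cycle segmentation, the second heart sound of each cycle is located
from the envelope burst structure, aligned to its onset, cut to a fixed
window, decimated to 10 kHz, and peak-normalized.  A PCA feature space is
fitted on within-session averaged S2 waveforms; temporal modes explaining
less than 5% of the variance are omitted, and individual sounds are
represented by their projection scores on the retained modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import PCA

from .segmentation import CycleSegmentation, _find_bursts, peak_normalize, rms_envelope

#: Target rate for S2 waveforms after decimation.
S2_TARGET_RATE_HZ = 10_000.0
#: Fixed S2 analysis window; covers the full S2 burst at murine heart rates.
S2_WINDOW_MS = 25.0
#: Minimum explained-variance fraction for a PCA mode to be retained.
VARIANCE_THRESHOLD = 0.05


@dataclass
class S2Record:
    """One onset-aligned, unit-peak S2 waveform with its provenance."""

    waveform: np.ndarray
    subject_id: str
    session_id: str
    label: str

    def __post_init__(self) -> None:
        peak = np.max(np.abs(self.waveform)) if self.waveform.size else 0.0
        if not np.isclose(peak, 1.0):
            raise ValueError(f"S2 waveform must be unit-peak normalized (peak={peak})")


@dataclass
class FeatureSpace:
    """Retained PCA temporal modes of within-session averaged S2 waveforms."""

    mean_waveform: np.ndarray
    components: np.ndarray          # (n_modes, n_samples), orthonormal rows
    explained_fractions: np.ndarray
    retained_indices: np.ndarray
    variance_threshold: float = VARIANCE_THRESHOLD

    @property
    def n_retained(self) -> int:
        return len(self.retained_indices)

    @property
    def retained_components(self) -> np.ndarray:
        return self.components[self.retained_indices]


@dataclass
class FeatureVector:
    """Projection scores of one sound on the retained modes."""

    scores: np.ndarray
    subject_id: str
    label: str


def preprocess(
    s2_raw: np.ndarray, rate_hz: float = 100_000.0, target_rate_hz: float = S2_TARGET_RATE_HZ
) -> np.ndarray:
    """Anti-alias low-pass, decimate to the target rate, peak-normalize.

    The decimation factor ``rate_hz / target_rate_hz`` must be an integer.
    """
    s2_raw = np.asarray(s2_raw, dtype=float)
    if s2_raw.size == 0 or np.max(np.abs(s2_raw)) == 0:
        raise ValueError("cannot normalize an all-zero S2 segment")
    factor = rate_hz / target_rate_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"rate {rate_hz} is not an integer multiple of {target_rate_hz}")
    factor = int(round(factor))
    out = sps.decimate(s2_raw, factor, ftype="fir", zero_phase=True) if factor > 1 else s2_raw
    return peak_normalize(out)


def isolate_s2(
    samples: np.ndarray,
    rate_hz: float,
    segmentation: CycleSegmentation,
    subject_id: str = "",
    session_id: str = "s1",
    label: str = "",
    burst_threshold_fraction: float = 0.25,
    window_ms: float = S2_WINDOW_MS,
    envelope_window_ms: float = 5.0,
) -> Tuple[List[S2Record], int]:
    """Cut one aligned S2 record per usable segmented cycle.

    Within each cycle the envelope bursts are the maximal runs above
    ``burst_threshold_fraction`` of the cycle's envelope maximum; the second
    burst is taken as S2, its first threshold crossing as the onset, and a
    fixed ``window_ms`` window from that onset as the waveform, which is then
    decimated to 10 kHz and normalized.  Cycles without two resolvable
    bursts are skipped; the skipped count is returned alongside the records.
    """
    if segmentation.n_cycles == 0:
        return [], 0
    samples = np.asarray(samples, dtype=float)
    env = rms_envelope(peak_normalize(samples), envelope_window_ms, rate_hz)
    win = int(round(window_ms * 1e-3 * rate_hz))
    records: List[S2Record] = []
    skipped = 0
    starts = segmentation.cycle_starts
    for i, start in enumerate(starts):
        end = starts[i + 1] if i + 1 < len(starts) else len(samples)
        cyc_env = env[start:end]
        bursts = _find_bursts(cyc_env, burst_threshold_fraction)
        if len(bursts) < 2:
            skipped += 1
            continue
        onset = int(start) + bursts[1][0]
        if onset + win > len(samples):
            skipped += 1
            continue
        seg = samples[onset : onset + win]
        if np.max(np.abs(seg)) == 0:
            skipped += 1
            continue
        records.append(
            S2Record(
                waveform=preprocess(seg, rate_hz),
                subject_id=subject_id,
                session_id=session_id,
                label=label,
            )
        )
    return records, skipped


def session_averages(records: Sequence[S2Record]) -> Tuple[np.ndarray, List[str]]:
    """Average the S2 waveforms within each (subject, session) pair."""
    keys: List[str] = []
    groups = {}
    for r in records:
        key = f"{r.subject_id}/{r.session_id}"
        groups.setdefault(key, []).append(r.waveform)
    mats = []
    for key in sorted(groups):
        keys.append(key)
        mats.append(np.mean(groups[key], axis=0))
    return np.asarray(mats), keys


def fit_feature_space(
    training_records: Sequence[S2Record], variance_threshold: float = VARIANCE_THRESHOLD
) -> FeatureSpace:
    """Fit PCA on within-session averaged S2 waveforms.

    All principal modes are computed (so explained fractions sum to one);
    modes below the variance threshold are excluded from the retained set
    used for classification features.
    """
    avgs, keys = session_averages(training_records)
    if len(keys) < 2:
        raise ValueError(f"need >= 2 sessions to fit a feature space, got {len(keys)}")
    pca = PCA(n_components=min(avgs.shape[0] - 1, avgs.shape[1]), svd_solver="full")
    pca.fit(avgs)
    fractions = pca.explained_variance_ratio_
    retained = np.nonzero(fractions >= variance_threshold)[0]
    return FeatureSpace(
        mean_waveform=pca.mean_,
        components=pca.components_,
        explained_fractions=fractions,
        retained_indices=retained,
        variance_threshold=variance_threshold,
    )


def project_waveform(waveform: np.ndarray, space: FeatureSpace) -> np.ndarray:
    """Retained-mode scores of one waveform (mean-centered inner products)."""
    waveform = np.asarray(waveform, dtype=float)
    if len(waveform) != space.components.shape[1]:
        raise ValueError(
            f"waveform length {len(waveform)} does not match feature-space length "
            f"{space.components.shape[1]}"
        )
    return space.retained_components @ (waveform - space.mean_waveform)


def project(record: S2Record, space: FeatureSpace) -> FeatureVector:
    """Score one S2 record on the retained modes."""
    scores = project_waveform(record.waveform, space)
    return FeatureVector(scores=scores, subject_id=record.subject_id, label=record.label)


def project_batch(records: Sequence[S2Record], space: FeatureSpace) -> List[FeatureVector]:
    """Project many records; equivalent to per-record :func:`project`."""
    if not records:
        return []
    waves = np.stack([r.waveform for r in records])
    scores = (waves - space.mean_waveform) @ space.retained_components.T
    return [
        FeatureVector(scores=s, subject_id=r.subject_id, label=r.label)
        for s, r in zip(scores, records)
    ]
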