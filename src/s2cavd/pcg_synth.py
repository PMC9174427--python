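"""Synthetic murine phonocardiogram generator.

Produces cohorts of anesthetized-mouse heart-sound recordings with paired
single-lead ECG traces and exact ground-truth annotations.  The generator
emulates the acoustic structure relevant to second-heart-sound (S2) analysis
in a chronic-kidney-disease (CKD) model of calcific aortic valve disease
(CAVD):

* ~125-150 ms cardiac cycles with systole shorter than diastole,
* S1 and S2 bursts modeled as exponentially decaying sinusoids with a
  Gaussian onset ramp,
* sporadic S3/S4 sounds and holosystolic murmurs at sub-percent per-cycle
  prevalence,
* slow respiratory baseline motion plus discrete respiratory movement
  artifacts, and
* a disease-dependent S2 morphology: CKD delays and amplifies the pulmonary
  sub-component (P2), while aortic-valve calcification distorts the aortic
  sub-component (A2) with a strength that grows monotonically with the
  planted calcification volume fraction.

All randomness flows through a ``numpy`` Generator seeded from the protocol
seed and a stable hash of the subject id, so identical protocols reproduce
bit-identical recordings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

GROUPS = ("Control", "Adenine", "Adenine+HP")
LABELS = ("Healthy", "CKD", "CKD+CAVD")

#: Calcification range (% of leaflet volume) observed across diseased valves;
#: used to truncate the planted right-skewed distribution.
CALCIFICATION_RANGE_PCT = (0.27, 39.03)


@dataclass(frozen=True)
class BurstParams:
    """Descriptor for one heart-sound burst (decaying sinusoid)."""

    center_freq_hz: float
    duration_ms: float
    amplitude: float


@dataclass(frozen=True)
class SynthProtocol:
    """Acquisition and physiology parameters for one synthetic recording.

    Defaults mirror the acquisition conditions the pipeline targets:
    100 kHz sampling for 60 s, a heart rate of 480 bpm under light
    anesthesia, and respiration at 1-2 movements per second.
    """

    sampling_rate_hz: float = 100_000.0
    duration_s: float = 60.0
    heart_rate_bpm: float = 480.0
    cycle_jitter_frac: float = 0.005
    systole_fraction: float = 0.35
    s1_params: BurstParams = field(default=BurstParams(150.0, 14.0, 1.0))
    s2_params: BurstParams = field(default=BurstParams(250.0, 12.0, 0.9))
    s3_prevalence: float = 0.0
    s4_prevalence: float = 0.0
    murmur_prevalence: float = 0.0
    respiration_rate_hz: float = 1.5
    n_artifacts: int = 1
    noise_snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.heart_rate_bpm <= 0:
            raise ValueError(f"heart_rate_bpm must be positive, got {self.heart_rate_bpm}")
        if not 0.0 < self.systole_fraction < 0.5:
            raise ValueError(
                "systole_fraction must lie in (0, 0.5) so that systole is "
                f"shorter than diastole, got {self.systole_fraction}"
            )
        for name in ("s3_prevalence", "s4_prevalence", "murmur_prevalence"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass
class PCGRecording:
    """A sampled acoustic trace tagged with subject identity."""

    samples: np.ndarray
    sampling_rate_hz: float
    subject_id: str
    session_id: str = "s1"

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz


@dataclass
class GroundTruth:
    """Exact annotations for one synthetic recording.

    ``r_peaks`` are expressed in the PCG timebase and coincide with
    ``cycle_starts``: the simulator's link between the ECG R-peak and the
    start of systole (onset of S1).
    """

    cycle_starts: np.ndarray
    s1_onsets: np.ndarray
    s2_onsets: np.ndarray
    artifact_spans: List[Tuple[int, int]]
    extra_sound_flags: Dict[str, np.ndarray]
    r_peaks: np.ndarray
    sampling_rate_hz: float
    n_samples: int

    @property
    def cycle_durations_samples(self) -> np.ndarray:
        return np.diff(self.cycle_starts)


@dataclass(frozen=True)
class SyntheticSubject:
    """One simulated mouse: diet group, sex, and planted disease state."""

    subject_id: str
    sex: str
    diet_group: str
    planted_calcification_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.diet_group not in GROUPS:
            raise ValueError(f"unknown diet group {self.diet_group!r}")
        if self.planted_calcification_pct < 0:
            raise ValueError("planted_calcification_pct must be >= 0")
        if self.diet_group in ("Control", "Adenine") and self.planted_calcification_pct > 0:
            raise ValueError(f"{self.diet_group} subjects must have zero planted calcification")

    @property
    def label(self) -> str:
        """Disease label implied by diet group and calcification burden."""
        if self.diet_group == "Control":
            return "Healthy"
        return "CKD+CAVD" if self.planted_calcification_pct > 0 else "CKD"

    @property
    def s2_effect_scale(self) -> float:
        return effect_scale_from_calcification(self.planted_calcification_pct)


def effect_scale_from_calcification(pct: float) -> float:
    """Map a calcification volume fraction (%) to an S2 distortion scale.

    Zero calcification maps to zero effect; positive burdens map to a
    saturating square-root ramp over the observed range, so mice with
    sub-percent mineral volume carry a barely detectable acoustic signature
    while heavily calcified valves distort S2 strongly.  The mapping is
    monotone nondecreasing on [0, inf).
    """
    if pct <= 0:
        return 0.0
    hi = CALCIFICATION_RANGE_PCT[1]
    return float(np.sqrt(min(pct, hi) / hi))


def _subject_rng(seed: int, subject_id: str, stream: str = "pcg") -> np.random.Generator:
    """Deterministic per-subject generator derived from the protocol seed."""
    h = zlib.crc32(f"{subject_id}/{stream}".encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, h])


def _burst(
    n: int,
    fs: float,
    onset: int,
    freq_hz: float,
    duration_ms: float,
    amplitude: float,
    out: np.ndarray,
) -> None:
    """Add one decaying-sinusoid burst (Gaussian onset ramp) in place."""
    dur = int(round(duration_ms * 1e-3 * fs))
    if dur <= 0 or onset >= n:
        return
    stop = min(onset + dur, n)
    t = np.arange(stop - onset) / fs
    t_pk = 1.5e-3
    sigma_r = 0.6e-3
    tau = duration_ms * 1e-3 / 4.0
    env = np.where(t < t_pk, np.exp(-0.5 * ((t - t_pk) / sigma_r) ** 2), np.exp(-(t - t_pk) / tau))
    out[onset:stop] += amplitude * env * np.sin(2 * np.pi * freq_hz * t)


def _add_s2(
    out: np.ndarray,
    fs: float,
    onset: int,
    params: BurstParams,
    label: str,
    effect_scale: float,
    amp_factor: float,
    rng: np.random.Generator,
) -> None:
    """Render the aortic (A2) + pulmonary (P2) sub-bursts of one S2 sound.

    CKD delays and amplifies P2; calcification adds a high-frequency A2
    component and widens the A2 envelope in proportion to ``effect_scale``.
    Sub-component timing and amplitudes jitter from sound to sound, so
    single S2 sounds overlap between classes even when session averages
    separate cleanly.
    """
    n = len(out)
    a2_dur = params.duration_ms
    a2_amp = params.amplitude * amp_factor * (1.0 + 0.06 * rng.standard_normal())
    p2_delay_ms, p2_amp = (5.5, 0.9) if label == "CKD" else (2.5, 0.55)
    p2_delay_ms = max(0.5, p2_delay_ms + 0.2 * rng.standard_normal())
    p2_amp = p2_amp * max(0.0, 1.0 + 0.08 * rng.standard_normal())
    if label == "CKD+CAVD":
        a2_dur = a2_dur * (1.0 + 0.6 * effect_scale)
        cavd_amp = 0.6 * effect_scale * amp_factor * max(0.0, 1.0 + 0.12 * rng.standard_normal())
        _burst(n, fs, onset + int(round(1e-3 * fs)), 520.0, 8.0, cavd_amp, out)
    _burst(n, fs, onset, params.center_freq_hz, a2_dur, a2_amp, out)
    p2_onset = onset + int(round(p2_delay_ms * 1e-3 * fs))
    _burst(n, fs, p2_onset, params.center_freq_hz * 1.3, params.duration_ms * 0.8,
           p2_amp * amp_factor, out)


def synthesize_recording(
    protocol: SynthProtocol, subject: SyntheticSubject
) -> Tuple[PCGRecording, GroundTruth]:
    """Render one phonocardiogram plus exact ground truth for a subject.

    Every cardiac cycle carries one S1 and one S2 burst; extra sounds are
    drawn per cycle as independent Bernoulli trials at the protocol
    prevalences.  Respiratory motion contributes a continuous low-amplitude
    baseline plus ``protocol.n_artifacts`` discrete broadband artifact bursts
    whose spans are recorded in the ground truth.
    """
    fs = protocol.sampling_rate_hz
    n = protocol.n_samples
    rng = _subject_rng(protocol.seed, subject.subject_id)
    label = subject.label

    signal = np.zeros(n)
    base_cycle = 60.0 / protocol.heart_rate_bpm

    cycle_starts: List[int] = []
    s2_onsets: List[int] = []
    s3_flags: List[bool] = []
    s4_flags: List[bool] = []
    murmur_flags: List[bool] = []

    t = 0.020  # lead-in before the first cycle
    while True:
        dur = base_cycle * (1.0 + protocol.cycle_jitter_frac * rng.standard_normal())
        dur = float(np.clip(dur, 0.7 * base_cycle, 1.3 * base_cycle))
        start = int(round(t * fs))
        end = int(round((t + dur) * fs))
        if end >= n:
            break
        systole = protocol.systole_fraction * dur
        s2_on = int(round((t + systole) * fs))

        amp_s1 = 1.0 + 0.05 * rng.standard_normal()
        amp_s2 = 1.0 + 0.05 * rng.standard_normal()
        _burst(n, fs, start, protocol.s1_params.center_freq_hz,
               protocol.s1_params.duration_ms, protocol.s1_params.amplitude * amp_s1, signal)
        _add_s2(signal, fs, s2_on, protocol.s2_params, label,
                subject.s2_effect_scale, amp_s2, rng)

        has_s3 = bool(rng.random() < protocol.s3_prevalence)
        has_s4 = bool(rng.random() < protocol.s4_prevalence)
        has_murmur = bool(rng.random() < protocol.murmur_prevalence)
        if has_s3:  # early-diastolic low-frequency sound
            _burst(n, fs, s2_on + int(round(0.25 * (dur - systole) * fs)),
                   110.0, 16.0, 0.35, signal)
        if has_s4:  # late-diastolic sound just before the next S1
            _burst(n, fs, end - int(round(0.014 * fs)), 95.0, 14.0, 0.4, signal)
        if has_murmur:  # holosystolic band-limited noise between S1 and S2
            m0 = start + int(round(0.005 * fs))
            m1 = max(m0 + 1, s2_on - int(round(0.002 * fs)))
            seg = rng.standard_normal(m1 - m0)
            carrier = np.sin(2 * np.pi * 300.0 * np.arange(m1 - m0) / fs)
            signal[m0:m1] += 0.18 * seg * np.abs(carrier)

        cycle_starts.append(start)
        s2_onsets.append(s2_on)
        s3_flags.append(has_s3)
        s4_flags.append(has_s4)
        murmur_flags.append(has_murmur)
        t += dur

    # Continuous respiratory baseline (abdomen motion under anesthesia).
    tt = np.arange(n) / fs
    signal += 0.02 * np.sin(2 * np.pi * protocol.respiration_rate_hz * tt + rng.uniform(0, 2 * np.pi))

    # Discrete respiratory movement artifacts: broadband low-frequency bursts
    # spanning roughly 1-2 cycles, placed away from the recording edges.
    artifact_spans: List[Tuple[int, int]] = []
    art_len = int(round(2.0 * base_cycle * fs))
    for _ in range(max(0, int(protocol.n_artifacts))):
        lo = int(0.25 * n)
        hi = max(lo + 1, int(0.85 * n) - art_len)
        a0 = int(rng.integers(lo, hi))
        a1 = min(a0 + art_len, n)
        burst = rng.standard_normal(a1 - a0)
        # low-pass shaping by cumulative smoothing keeps energy below ~100 Hz
        kernel = np.hanning(max(3, int(0.01 * fs)))
        kernel /= kernel.sum()
        shaped = np.convolve(burst, kernel, mode="same")
        shaped *= np.hanning(a1 - a0)
        peak = np.max(np.abs(shaped))
        if peak > 0:
            signal[a0:a1] += 1.5 * shaped / peak
        artifact_spans.append((a0, a1))

    rms = float(np.sqrt(np.mean(signal**2)))
    noise_std = rms * 10 ** (-protocol.noise_snr_db / 20.0)
    signal += noise_std * rng.standard_normal(n)

    starts = np.asarray(cycle_starts, dtype=np.int64)
    truth = GroundTruth(
        cycle_starts=starts,
        s1_onsets=starts.copy(),
        s2_onsets=np.asarray(s2_onsets, dtype=np.int64),
        artifact_spans=artifact_spans,
        extra_sound_flags={
            "s3": np.asarray(s3_flags, dtype=bool),
            "s4": np.asarray(s4_flags, dtype=bool),
            "murmur": np.asarray(murmur_flags, dtype=bool),
        },
        r_peaks=starts.copy(),
        sampling_rate_hz=fs,
        n_samples=n,
    )
    rec = PCGRecording(samples=signal, sampling_rate_hz=fs, subject_id=subject.subject_id)
    return rec, truth


def synthesize_paired_ecg(
    truth: GroundTruth, ecg_rate_hz: float = 24_414.0, seed: int = 0
) -> np.ndarray:
    """Simulate the simultaneously recorded single-lead ECG.

    One dominant R-peak is placed per ground-truth cycle start, converted
    from the PCG timebase by rate-ratio rounding, so peak indices convert
    back to PCG sample indices to within one sample.
    """
    if ecg_rate_hz <= 0:
        raise ValueError("ecg_rate_hz must be positive")
    n_ecg = int(round(truth.n_samples / truth.sampling_rate_hz * ecg_rate_hz))
    ecg = np.zeros(n_ecg)
    if len(truth.r_peaks) == 0 or n_ecg == 0:
        return ecg
    rng = np.random.default_rng(seed)
    ratio = ecg_rate_hz / truth.sampling_rate_hz
    peaks = np.round(truth.r_peaks * ratio).astype(np.int64)
    width = max(1, int(round(1.5e-3 * ecg_rate_hz)))
    half = 3 * width
    for p in peaks:
        i0, i1 = max(0, p - half), min(n_ecg, p + half + 1)
        t = np.arange(i0 - p, i1 - p)
        ecg[i0:i1] += np.exp(-0.5 * (t / width) ** 2)
        # small T-wave bump after the R-peak
        tw = p + int(round(0.030 * ecg_rate_hz))
        j0, j1 = max(0, tw - 4 * width), min(n_ecg, tw + 4 * width)
        if j1 > j0:
            tt = np.arange(j0 - tw, j1 - tw)
            ecg[j0:j1] += 0.15 * np.exp(-0.5 * (tt / (2 * width)) ** 2)
    ecg += 0.02 * rng.standard_normal(n_ecg)
    return ecg


@dataclass(frozen=True)
class CohortSpec:
    """Per-group sex composition and disease parameters for a cohort.

    The default composition matches a post-attrition study cohort of 24
    mice: Control 6M+5F, Adenine 4M, Adenine+HP 5M+4F, with every
    Adenine+HP mouse carrying a positive calcification burden drawn from a
    right-skewed (lognormal) distribution truncated to the observed
    0.27-39.03% range.
    """

    composition: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {
            "Control": (6, 5),
            "Adenine": (4, 0),
            "Adenine+HP": (5, 4),
        }
    )
    calcification_lognorm_mu: float = np.log(7.0)
    calcification_lognorm_sigma: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for grp, (m, f) in self.composition.items():
            if grp not in GROUPS:
                raise ValueError(f"unknown group {grp!r}")
            if m < 0 or f < 0:
                raise ValueError(f"negative count for {grp}: ({m}, {f})")


def draw_calcification(
    rng: np.random.Generator,
    size: int,
    mu: float = np.log(7.0),
    sigma: float = 0.9,
    bounds: Tuple[float, float] = CALCIFICATION_RANGE_PCT,
) -> np.ndarray:
    """Draw right-skewed calcification percentages truncated by resampling."""
    lo, hi = bounds
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, sigma, size=2 * (size - filled))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def synthesize_cohort(spec: Optional[CohortSpec] = None) -> List[SyntheticSubject]:
    """Create the subject table for a synthetic cohort.

    Recordings are rendered per subject on demand via
    :func:`synthesize_recording` (the workbench drives this), keeping cohort
    creation cheap and memory bounded.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed & 0x7FFFFFFF)
    subjects: List[SyntheticSubject] = []
    idx = 1
    for grp in GROUPS:
        m, f = spec.composition.get(grp, (0, 0))
        sexes = ["M"] * m + ["F"] * f
        if grp == "Adenine+HP" and sexes:
            calc = draw_calcification(
                rng, len(sexes), spec.calcification_lognorm_mu, spec.calcification_lognorm_sigma
            )
        else:
            calc = np.zeros(len(sexes))
        for sex, pct in zip(sexes, calc):
            subjects.append(
                SyntheticSubject(
                    subject_id=f"m{idx:02d}",
                    sex=sex,
                    diet_group=grp,
                    planted_calcification_pct=float(pct),
                )
            )
            idx += 1
    return subjects


def group_protocol(base: SynthProtocol, subject: SyntheticSubject) -> SynthProtocol:
    """Attach the group-specific extra-sound prevalences to a protocol.

    Per-cycle prevalences follow the observed murmur/extra-sound rates:
    diastolic extra sounds in 1.10% of Control cycles (S3), 3.94% of Adenine
    cycles (S4), and in the calcified group 0.87% S3 plus 0.82% holosystolic
    murmurs.
    """
    if subject.diet_group == "Control":
        return replace(base, s3_prevalence=0.011, s4_prevalence=0.0, murmur_prevalence=0.0)
    if subject.diet_group == "Adenine":
        return replace(base, s3_prevalence=0.0, s4_prevalence=0.0394, murmur_prevalence=0.0)
    return replace(base, s3_prevalence=0.0087, s4_prevalence=0.0, murmur_prevalence=0.0082)
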