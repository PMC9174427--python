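# Methods

`s2cavd` re-implements, as a tested pipeline, an analysis chain that detects
aortic-valve calcification (CAVD) in mice from the second heart sound (S2):
template-matching segmentation of phonocardiograms (PCG), S2 isolation and
PCA feature reduction, a bagged classification-tree ensemble evaluated under
subject-wise leave-p-out cross-validation, and volumetric quantification of
valve calcification that defines the class labels. Because no recordings are
deposited with the source study, a synthetic-data generator provides inputs
with the statistical structure the analysis assumes; every stage is testable
end to end without downloads.

## Synthetic phonocardiograms (`pcg_synth`)

**Model.** A recording is a train of cardiac cycles. Cycle duration is
`60 / heart_rate_bpm` with multiplicative Gaussian jitter; systole occupies
`systole_fraction` of each cycle (default 0.35, enforcing systole shorter
than diastole). Each cycle carries an S1 burst at its start and an S2 burst
at the end of systole. Bursts are exponentially decaying sinusoids with a
Gaussian onset ramp — a standard phonocardiogram phantom that gives
unambiguous onsets. S2 is the sum of an aortic (A2) and a pulmonary (P2)
sub-burst.

**Disease signatures.** Chronic kidney disease (CKD) delays and amplifies
P2 (2.5 → 5.5 ms delay, 0.55 → 0.9 relative amplitude), motivated by the
expected pulmonary-pressure changes in CKD. Calcification distorts A2: a
520 Hz component is added and the A2 envelope widened, both in proportion to
an effect scale `sqrt(pct / 39.03)` of the planted calcification volume
fraction `pct` (zero at zero burden, saturating at the top of the observed
0.27–39.03% range). The square-root ramp was chosen so that sub-percent
burdens carry a barely detectable signature while heavy calcification is
obvious; it is monotone, which is all downstream analyses rely on. An
earlier variant with a constant offset at any positive burden made every
diseased mouse trivially classifiable and destroyed the accuracy-vs-burden
gradient the evaluation module is designed to expose.

**Per-sound variability.** Sub-component morphology jitters from sound to
sound (A2 amplitude 6%, P2 delay 0.2 ms, P2 amplitude 8%, calcific
component amplitude 12%, all Gaussian), on top of the additive recording
noise. These magnitudes were calibrated between two degenerate regimes:
with no morphological jitter every ensemble vote is unanimous (one-hot vote
fractions, degenerate ROC, no accuracy-vs-burden gradient), while at twice
these values the classes overlap so heavily that even the best split cannot
reach the published performance range. At the chosen values single sounds
overlap between classes, vote fractions are graded, and the subject-wise
sweep exhibits the accuracy-vs-calcification gradient the evaluation module
is designed to expose.

**Extra sounds and artifacts.** Per cycle, S3, S4, and holosystolic-murmur
events are independent Bernoulli draws; default per-group prevalences follow
the observed per-cycle rates (Control 1.10% S3; CKD 3.94% S4; calcified
group 0.87% S3 + 0.82% murmur). Respiration contributes a continuous
low-amplitude baseline at `respiration_rate_hz` (default 1.5 Hz, matching
1–2 abdomen movements/s under anesthesia) plus `n_artifacts` discrete
broadband movement bursts spanning ~2 cycles (default 1 per recording).
Modeling every breath as a disruptive artifact would corrupt nearly all
cycles at 1.5 Hz, which contradicts the segmentation performance the method
achieves on real data; only occasional movements are disruptive.

**Key defaults.** 100 kHz sampling, 60 s duration, 480 bpm, SNR 20 dB,
cycle jitter 0.5%. The jitter default reflects the regularity of
anesthetized mice (reported mean cycle duration 147.08 ± 1.80 ms across
animals; within-recording variability is smaller). At 2% jitter the S2 burst
drifts several milliseconds between template and target cycles, which makes
envelope template matching fail in a way the real data evidently does not.

**Cohort.** The default cohort is 24 mice — Control 6M+5F, Adenine (CKD
diet) 4M, Adenine+HP (CKD + high phosphate, calcified) 5M+4F — the
post-attrition composition of the target experiment. Calcification burdens
for Adenine+HP mice are lognormal (median 7%, σ=0.9 in log-space) truncated
by resampling to [0.27, 39.03]%; the other groups have zero burden.
Determinism: all randomness flows through a generator seeded by
(protocol seed, CRC32 of subject id), so identical protocols reproduce
bit-identical recordings.

## ROI-SSE segmentation (`segmentation`)

The operator (or, for synthetic data, a ground-truth-guided helper) selects
a region of interest (ROI) spanning one cardiac cycle. The ROI is accepted
only if its envelope shows two bursts whose spacing makes systole shorter
than diastole. The recording is peak-normalized, its RMS envelope computed
over a 5 ms window (shorter than a heart-sound burst, longer than the
carrier period), and the sum-of-squares error (SSE) between the ROI envelope
and the recording envelope evaluated at every offset where the ROI fits
(no padding — padded offsets would fabricate error values).

Cycle starts are local SSE minima below a threshold, accepted greedily in
increasing-error order subject to a minimum separation of 0.6 × ROI length
(preventing duplicate detections inside one cycle). The classic absolute
threshold (SSE < 10 on the peak-normalized scale) is the library default,
but it is sensitive to the peak-normalization scale: a recording whose
global peak is a movement artifact has a compressed envelope and small
absolute SSE everywhere, while a clean recording does not. The pipeline
therefore defaults to the scale-free relative form — threshold = 0.1 × the
profile median. With it, clean synthetic recordings yield 100% cycle-start
recovery and a mean-cycle-duration disagreement with the ECG reference of
~0.002 ms (the method reports 0.004 ms on real data), and artifact-bearing
recordings lose only the artifact-overlapped cycles, reproducing the
direction of the ROI-SSE-vs-ECG cycle deficit.

The SSE profile is computed two ways: an exact windowed subtraction for
small problems and an overlap-add convolution expansion
(`sum roi² − 2·crosscorr + windowed sum rec²`) for long recordings; the two
agree to 1e-9 relative and the equivalence is asserted in tests against an
independent double-loop oracle. The profile argmax locates the respiratory
artifact (ties break to the smallest offset).

The ECG reference segmentation picks R-peaks with robust height thresholds
and a 50 ms refractory period, then converts peak indices to the PCG
timebase by nearest-sample rounding (half-ties round down).

**Count-error reporting.** The comparison report gives both the raw cycle
count difference and its normalized form (|Δcount| / max count); the source
analysis prints a count "absolute error" (0.063 ± 0.007) that cannot be
reconciled with its own raw deficit (7.75 cycles) under any single
normalization, so neither form is privileged here.

## S2 features (`s2_features`)

Within each segmented cycle, envelope bursts are maximal runs above 25% of
the cycle's envelope maximum; the second burst is S2, its first threshold
crossing the onset. A fixed 25 ms window from the onset (covering the full
S2 burst at murine rates) is cut, anti-alias filtered and decimated to
10 kHz, then peak-normalized (downsample → normalize; the opposite order
differs only by the scale constant). Cycles without two resolvable bursts
are skipped and counted.

PCA is fitted on within-session averaged S2 waveforms (mean-centered, full
SVD, so explained fractions sum to one). Temporal modes explaining < 5% of
variance are omitted. Individual sounds — not session averages — are
projected on the retained modes, and those per-sound scores are the
classifier inputs: per-sound classification requires per-sound features,
which is the only reading consistent with sound-level confusion tables.
Test sounds are always projected on the training-set space, never refitted.

## Classifier (`classifier`)

Trees are implemented in-repo because two contracts are nonstandard:

* **Partition bagging.** Each of the 60 trees draws its in-bag sample
  *without replacement* as exactly round(2/3 · n) sounds; the remaining
  third is out-of-bag (OOB). A classical bootstrap mode exists behind
  `bootstrap=True`.
* **Node cap.** Tree growth (best-first by weighted impurity) stops when
  the number of split nodes reaches the retained-feature count d, or at
  purity. ceil(√d) random features are considered per node; splits use Gini
  impurity.

All tie-breaks are deterministic: split ties to the lowest feature index
then lowest threshold, vote ties to the lowest class index in the fixed
order Healthy < CKD < CKD+CAVD. OOB error (overall and per class) uses only
votes of trees that did not hold the sample in-bag; samples never OOB are
excluded and counted. Ensembles serialize to JSON and round-trip to
identical predictions.

## Evaluation (`evaluation`)

Test sets follow a fixed composition — 1M+1F Healthy, 1M CKD, 1M+1F
CKD+CAVD — and all of a subject's sounds stay on one side (subject-wise
splitting; record-wise splits would confound identity with disease). All
admissible test sets are enumerated (the default cohort yields
6·5·4·5·4 = 2,400 plans); sweeps may run all plans or a seeded subsample,
with per-plan seeds derived deterministically from (global seed, plan id).
The final model is the plan minimizing the summed per-group
misclassification (ties to the lowest plan id).

Multiclass ROC is one-vs-rest per class with the ensemble vote fraction as
the score and trapezoid integration (equal to the normalized Mann–Whitney
statistic; asserted against an independent implementation in tests). The
confusion report is predicted-by-true, row-normalized to percent, with PPV
per disease class, NPV for Healthy, and disease-binarized TP/TN/FP/FN
counts and shares (positive = CKD or CKD+CAVD — the only binarization
consistent with the published share arithmetic, whose printed TP *count* is
internally inconsistent with its own percentage and is not reproduced).
Pearson correlation links per-plan CKD+CAVD accuracy to the mean
calcification burden of CKD+CAVD mice on either side of the split.

## Valve imaging (`valve_imaging`)

Both channels of a cusp Z-stack are binarized with one common strict
threshold per dataset run. Percent calcification by volume is
100 · |probe-positive ∩ leaflet| / |leaflet|; restricting probe positivity
to the leaflet mask bounds the percentage by 100 (the quantity is ill-posed
otherwise). Voxels are counted without Z-anisotropy correction, matching
count-based quantification. Subject burden is the volume-weighted mean over
available cusps (unweighted available). Labels: Control → Healthy;
adenine-diet subjects → CKD+CAVD if burden > 0%, CKD if exactly 0%.

The synthetic stack generator plants `round(f · leaflet_volume)` positive
voxels as clustered blobs near the leaflet base of an ellipsoidal leaflet,
so recovery is exact up to one-voxel quantization.

## Workbench and problem sizes

`run_pipeline` chains simulate → label (from synthetic stacks by default) →
segment → isolate → sweep → select → report, with a manifest recording
per-stage timings, per-subject cycle/sound counts, and warnings. A single
global seed fans out to stages by stable hashing of stage names.

Default pipeline problem sizes are desk-scale by design: recordings at
20 kHz for 12 s (≈ 95 cycles/mouse, ≈ 2,200 S2 sounds per cohort — the same
order as the 2,516-sound target dataset) and a 60-plan sweep. Statistical
conclusions (AUC ranges, correlation signs, OOB levels) are insensitive to
these sizes; the full 100 kHz / 60 s / 2,400-plan configuration is a config
change. Full-acquisition-scale behavior is exercised directly by the
segmentation acceptance tests.

## What the synthetic data does not show

The generator emulates timing structure, burst morphology, disease effect
coupling, extra-sound prevalences, and artifact structure — not murine
thoracic acoustics, anesthesia pharmacology, or real inter-subject
morphology variance. Passing tests therefore demonstrate that the
*algorithms* behave as specified under the stated statistical structure
(e.g., that subject-wise evaluation exposes an accuracy-vs-burden gradient),
not that the published effect sizes would be recovered from new animal
recordings. Headline numbers that depend on the real recordings (the
published AUCs of 0.9940/0.9717/0.9593, the ±0.73 correlations) are
reproduced at the level of structure and sign, not value.

## Known limitations

* ROI selection is ground-truth-guided for synthetic data; on real WAV
  input the operator must supply ROI bounds (`s2calc segment --roi-start
  --roi-end`).
* The absolute SSE threshold is scale-dependent (see above); prefer the
  relative form for heterogeneous recordings.
* A2/P2 sub-component decomposition and frequency-domain features are out
  of scope, as are per-subject (majority-vote) diagnoses.
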