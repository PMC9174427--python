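# s2cavd

Detection of aortic-valve calcification from the second heart sound (S2)
in a mouse model of chronic kidney disease (CKD), implemented as a tested,
reusable Python pipeline.

Calcific aortic valve disease (CAVD) stiffens the aortic leaflets and
alters the acoustics of aortic valve closure — the aortic component of S2.
This package implements the full analysis chain needed to test whether S2
features identify valve calcification in murine phonocardiograms, for
researchers working on heart-sound biomarkers and small-animal models of
valve disease:

1. **ROI-SSE segmentation** — a one-cycle region of interest (ROI) is
   selected, and the sum-of-squares error (SSE) between the RMS envelope of
   the ROI and the envelope of the whole recording is evaluated at every
   alignment offset: low-SSE minima mark cycle starts, the SSE maximum
   marks a respiratory movement artifact. An ECG R-peak reference
   segmentation verifies the result.
2. **S2 features** — per cycle, the second envelope burst is isolated,
   onset-aligned, cut to 25 ms, decimated to 10 kHz, and peak-normalized.
   PCA is fitted on within-session averaged waveforms; temporal modes with
   ≥ 5% explained variance are retained and per-sound projection scores are
   the classifier inputs.
3. **Classification** — a bagged ensemble of 60 axis-aligned decision
   trees; each tree trains on an in-bag 2/3 partition of the training
   sounds (out-of-bag third used for the OOB error), considers ⌈√d⌉ random
   features per node, and is capped at d split nodes, where d is the
   retained-mode count.
4. **Evaluation** — subject-wise leave-p-out cross-validation over every
   admissible test set (1M+1F Healthy, 1M CKD, 1M+1F CKD+CAVD; 2,400 plans
   for the default cohort), per-sound accuracy per group, one-vs-rest
   ROC/AUC, a predicted-by-true confusion report with PPV/NPV, and the
   correlation between accuracy and mean calcification burden.
5. **Valve imaging** — percent calcification by volume from two-channel
   confocal Z-stacks (calcium-probe voxels within the autofluorescence
   leaflet mask, one common threshold per run), and the labeling rule:
   Control → Healthy; adenine-diet mice → CKD+CAVD if burden > 0%, CKD
   otherwise.

A synthetic-data module (`pcg_synth`, plus a stack generator in
`valve_imaging`) generates phonocardiograms with paired ECG, exact ground
truth, and planted calcification fractions, so the entire chain runs and is
tested without any animal recordings. See `docs/methods.md` for the models,
defaults, and their rationale.

## Worked example

Run the full synthetic pipeline (simulate → segment → isolate S2 → label →
sweep splits → select final model → report) from the shell:

```sh
s2calc run-all --seed 7 --sweep 12
```

```json
{
  "final_plan_id": 972,
  "auc_ovr": {
    "Healthy": 0.9612107105759242,
    "CKD": 0.9731182795698925,
    "CKD+CAVD": 0.9624227799227799
  },
  "final_oob_error": 0.08361774744027303,
  "sounds_per_group": {
    "Healthy": 1021,
    "CKD": 372,
    "CKD+CAVD": 830
  },
  "warnings": []
}
```

Reading the output: the simulated 24-mouse cohort yielded 2,223 S2 sounds
(1,021 Healthy / 372 CKD / 830 CKD+CAVD). Twelve subject-wise split plans
were swept; plan 972 minimized the summed per-group misclassification and
became the final model. On that plan's held-out mice the one-vs-rest AUCs
are ≈ 0.96–0.97 per class, and the final model's out-of-bag error on its
training sounds is ≈ 8.4%. The same entry points are available as library
calls (`s2cavd.workbench.run_pipeline`), and `s2calc simulate | segment |
quantify` expose the individual stages for real WAV/TIFF inputs.

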