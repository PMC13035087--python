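# vrnirs

A tested analysis pipeline for prefrontal functional near-infrared
spectroscopy (fNIRS) in pre/post intervention pain studies — the setting
where an 8-channel forehead montage records dual-wavelength (760/850 nm)
light intensities at 10 Hz while participants perform movement-evoked pain
tasks and immersive VR relaxation/distraction blocks, before and after an
at-home VR pain-management program.

No such dataset ships with this repository: a first-class synthetic-data
generator produces raw recordings and behavioral score tables with the full
statistical structure the analysis assumes (planted activation amplitudes,
planted channel-pair coactivation, planted brain–behavior correlations,
physiological noise, motion artifacts, and missing/invalid recordings), and
exports the ground truth so every stage is testable end to end.

## What the pipeline computes

**Preprocessing** (per recording): raw intensities → optical density
`ΔOD(c, λ, t) = −ln(I / mean_t I)` → motion-artifact flagging (0.5 s sliding
window, amplitude criterion 0.1 OD, 5-SD variability criterion, ±1 s mask
expansion) → zero-phase third-order Butterworth band-pass (0.01–0.2 Hz) →
modified Beer–Lambert inversion

```
ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · L · DPF(λ)
```

with age-adjusted differential pathlength factors, yielding ΔHbO/ΔHbR in μM
with a per-sample validity mask. Flagged samples are masked, never repaired.

**Subject level** (per recording, HbO only):

- GLM activation betas: OLS of HbO on condition boxcars convolved with the
  canonical double-gamma HRF (peak 6 s, undershoot 16 s), peak-normalized so
  β is in μM; regressors are passed through the same band-pass as the data.
- Effect size: Cohen *d* = (condition mean − 10 s prestimulus-baseline mean)
  / pooled SD, per channel and condition.
- Functional coactivation: Pearson *r* of HbO for all 28 unordered channel
  pairs within each condition's span, enumerated FC1=(1,2) … FC28=(7,8),
  with region-pair averages over the montage (channels 1–2 right lateral,
  3–4 right medial, 5–6 left medial, 7–8 left lateral PFC).

**Group level**: paired *t* tests on pre→post change (channels × conditions;
Fisher-z transformed coactivation pairs; behavioral instruments), reported
as (MD, t, P, q, paired d = MD/SD(diff), n) with Benjamini–Hochberg FDR per
family; Pearson brain–behavior correlations on change scores; sensitivity
analyses (Spearman time-since-injury screens with BH correction,
leave-one-out, ANCOVA on baseline + time since injury + injury type); and a
feasibility ledger of valid/missing/invalid recordings.

## Worked example

The numbered drivers under `analysis/` run the full study-sized analysis on
a simulated cohort of 10 subjects × 2 visits (bundles under `scratch/`,
tables under `results/`):

```bash
python analysis/01_simulate_cohort.py   # raw bundles + behavioral + truth
python analysis/02_preprocess_qc.py     # preprocessing + feasibility ledger
python analysis/03_subject_metrics.py   # betas, Cohen d, coactivation
python analysis/04_group_inference.py   # paired tests, BH-FDR, brain-behavior
python analysis/05_sensitivity.py       # Spearman / leave-one-out / ANCOVA
```

A run of `02` and `04` prints, among other lines:

```
80 scheduled recordings: 74 valid (93%), 5 missing, 1 invalid
QC status agrees with planted status for 80/80 recordings
...
-- neural changes with q < .05: 1 rows --
  fc distraction FC21: MD=+0.404, t=5.404, P=0.0010, q=0.0281
planted link (ch4 distraction beta change vs NRS-activity, r=0.76): recovered r=0.565 at n=8
```

Reading this: the pipeline's own quality control recovers the planted
feasibility pattern (74 of 80 recordings valid, 93%); the planted
post-treatment increase in right-medial–left-lateral coactivation during VR
distraction (pair FC21) survives FDR correction across the 28 pairs; and
the planted brain–behavior correlation is recovered attenuated (0.565 vs
0.76 planted) because at n=8 the measured neural change score carries
estimation noise on top of the planted change — exactly the behavior a
10-participant pilot should exhibit.

The same machinery is scriptable through the `vrnirs` CLI
(`simulate`, `preprocess`, `analyze`, `report`, `run-pipeline`), each
subcommand taking a single YAML config that is hashed into every output.

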