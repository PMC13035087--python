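# Methods

This note documents the models, parameter choices, and numerical decisions
behind the pipeline, and what the synthetic cohorts do and do not emulate.

## Signal model and preprocessing

Optical density uses the natural log against the per-channel,
per-wavelength time mean: `ΔOD = −ln(I / mean_t I)`. The reference-mean
convention makes OD scale-free, so the simulator's baseline intensity
(1.0, arbitrary units) is unobservable downstream; by Jensen's inequality
the time mean of ΔOD is ≥ 0, zero only for a constant signal.

Motion artifacts are *flagged, not repaired*. A sliding window of
`t_motion` = 0.5 s marks all its samples when either the window's
peak-to-peak OD exceeds `amp_thresh` = 0.1 OD (strict inequality) or the
standard deviation of sample-to-sample differences inside the window
exceeds `sd_thresh` = 5 times the record-wide SD of differences. Flags are
expanded by ±`t_mask` = 1 s and unioned over a channel's two wavelengths.
The mask is monotone in both thresholds (lowering either never shrinks it).
Masked samples are excluded from every downstream statistic (GLM rows,
effect-size and correlation windows); no spline or wavelet repair is
applied. Pre-marked manual exclusion spans merge into the same mask.

Filtering is a third-order Butterworth band-pass, 0.01–0.2 Hz, applied
forward–backward (zero phase — the dominant convention, and it preserves
event alignment). Implementation detail: the filter runs as second-order
sections because the transfer-function form is numerically ill-conditioned
at a normalized low cutoff of 0.002. Before filtering, masked spans are
bridged by linear interpolation *of the filter input only*: without this,
ringing from large artifacts leaks far beyond the mask into valid samples.
Bridged samples remain masked and excluded from all statistics; on a clean
recording the bridge is the identity. Note that the 0.01 Hz band edge's
poles ring for hundreds of seconds, so spectral verification excludes long
transients.

The modified Beer–Lambert law is inverted per channel and sample from the
2×2 extinction system over 760/850 nm. Extinction coefficients
(cm⁻¹ mM⁻¹): ε_HbO = 1.4866, ε_HbR = 3.8437 at 760 nm; ε_HbO = 2.5264,
ε_HbR = 1.7986 at 850 nm — a single pinned tabulation shared by the
forward simulator and the inversion, so round-trip correctness is
independent of the particular table. Source–detector separation defaults
to 3.5 cm (configurable; round-trip tests use the configured value). The
differential pathlength factor uses the general age- and
wavelength-dependent equation

```
DPF(age, λ) = 223.3 + 0.05624·age^0.8493 − 5.723e−7·λ³ + 0.001245·λ² − 0.9025·λ
```

monotone increasing in age. Over ages 18–80 it spans ≈ 5.96–7.63 at 760 nm
and ≈ 4.86–6.53 at 850 nm; over the default cohort age band (46.8 ± 11.86
years) it spans ≈ 6.1–7.4 at 760 nm. Instrument software that reports a
single DPF range of 6.00–6.61 presumably uses a different (unpublished)
age mapping; the formula here is pinned in configuration and the range it
produces is documented by a test rather than assumed.

Filtering operates on OD before the MBLL inversion. Both orders are
mathematically equivalent because both maps are linear; a test asserts the
commutation to 1e-9 μM.

## Task design and subject-level measures

The session design is: movement-evoked pain on the noninjured limb, then
the injured limb — each 10 hold–move–hold cycles, every cycle contributing
two 5 s holds (move 2.5 s, relax 3 s) — then a 2-minute rest and two
6-minute VR blocks (relaxation, then distraction), with short lead-in and
inter-block rests. Block membership is half-open `[onset, onset+duration)`.

GLM regressors are condition boxcars convolved with the canonical
double-gamma HRF (gamma-density difference with peaks at 6 s and 16 s,
undershoot ratio 1/6, kernel length 32 s), peak-normalized so the fitted
beta is in signal units (μM). Nuisance columns: intercept and linear
drift. Condition regressors are passed through the same zero-phase
band-pass as the data (matched filtering). This is what makes noise-free
recovery exact: filtered data remain in the span of filtered regressors,
so planted betas return to ~1e-8 μM; without it the 0.01 Hz high-pass
attenuates block content and biases betas, most severely for the single
long VR blocks. Estimation is per-channel OLS restricted to valid samples;
channels with fewer than k+2 valid rows or a rank-deficient masked design
yield missing values with a logged warning, never exceptions. Subject-level
t values are descriptive only (no prewhitening); group inference uses only
betas, d, and coactivation values.

Cohen *d* compares the condition-sample mean with the mean of a 10 s
prestimulus baseline window (configurable), divided by the pooled SD of
the two intervals. The denominator is switchable to baseline-only SD; the
pooled form is the default because paired comparisons of a long window
against a short baseline are otherwise dominated by the baseline's noisy
SD. Positive d means HbO rose during the condition.

Coactivation is the Pearson correlation of HbO between channel pairs
within a condition's span, over jointly valid samples (≥ 10 required).
Pairs are enumerated lexicographically — FC1=(1,2) … FC7=(1,8), FC8=(2,3),
…, FC28=(7,8). With the montage's region map (channels 1–2 right lateral,
3–4 right medial, 5–6 left medial, 7–8 left lateral) this enumeration
reproduces the conventional anatomical pair labels (e.g. FC21=(4,7) is
right medial – left lateral); it is the unique 2-per-region assignment
consistent with the printed channel and pair labels, and a structural test
pins all five identities. Region-pair values average the four inter-region
channel pairs (the single intra-region pair within a region).

## Group inference

Paired t tests operate on complete pre/post pairs (pairwise deletion, no
imputation): MD = mean(post − pre), t = MD/(SD(diff)/√n), two-sided p with
df = n − 1, paired d = MD/SD(diff) (this identity holds on every output
row). Coactivation values are Fisher z-transformed before the test and the
mean difference is back-transformed for reporting; a config switch
restores the raw-r pathway. BH-FDR is applied within families — 8 channels
per condition and metric, 28 pairs per condition, the behavioral battery
as one family — and the family label is recorded with each q.

The behavioral battery mirrors the standard instruments with their scale
ranges: NRS rest/activity (0–10), DVPRS interference items (0–10), PCS-13
(0–52), PASS-20 (0–100), PSEQ (0–60), CAMS-R (12–48), MOCS (0–52).

Sensitivity analyses: Spearman rank correlations of time since injury
against baseline values and change scores with BH correction;
leave-one-out re-estimation of paired tests reporting the fold extrema;
ANCOVA as OLS of the post value on baseline + time since injury + injury
type (categorical, collapsed), dropping constant covariates with a
warning. The robust-regression variant is deliberately out of scope (no
estimator is specified for it).

The feasibility ledger counts scheduled recordings by status; the valid
percentage rounds half-up (74/80 = 92.5% reports as 93%).

## The synthetic cohort

`simulate_subject` is the exact inverse of the preprocessing chain:
planted per-channel, per-condition amplitudes (μM) scale the same
peak-normalized HRF regressors the GLM uses; HbR is the canonical −1/3
counterpart of the planted HbO; the same MBLL constants produce OD; and
intensities are `exp(−OD)` about a unit baseline. With all noise at zero
the full pipeline returns the planted betas to numerical precision — the
round-trip contract behind the recovery tests.

Noise terms (defaults chosen as realistic magnitudes for forehead fNIRS;
neither channel-level noise magnitudes nor artifact rates are published
for this paradigm, so they are testability choices, not hardware fits):
cardiac 1.1 Hz at 0.3 μM, respiration 0.25 Hz at 0.2 μM, Mayer waves
0.1 Hz at 0.3 μM, linear drift 0.002 μM/s, white noise 0.15 μM, motion
artifacts 0.5/min at 0.3 OD (half spikes, half transient baseline
shifts). The oscillations are quasi-periodic: each tone's phase
random-walks at 0.3 rad/√s. Fixed-phase tones would correlate across
channels at cos(Δφ) indefinitely and flood the coactivation null with
spurious structure that real, drifting physiology does not produce;
phase diffusion restores realistic decorrelation. A pure-tone setting
(jitter 0) remains available and is what the spectral oracle test uses.

Planted coactivation mixes a band-limited latent signal into a chosen
channel set, optionally gated to one condition's span (state-related
coactivation). The default post-visit truth raises channel 4's VR betas by
0.15 μM and triples the (4,7) distraction component — the direction of the
study's reported findings.

Cohorts draw per-subject betas around the population truth
(between-subject SD 0.08 μM, change SD 0.08 μM). The linked behavioral
instrument's change score is sampled jointly with the linked neural change
score as a bivariate normal at the planted correlation; all scores are
affine-clipped into instrument range, and the clipping fraction is logged
because clipping attenuates the planted r (with the default battery ~9% of
scores clip, attenuating a planted 0.9 to ~0.88–0.90 at n=200; the
least-clipped instrument, CAMS-R, is used for recovery checks). Ages are
N(46.8, 11.86²) truncated to [18, 80]; time since injury N(38.4, 36.33²)
days floored at 3; injury type 90% fracture. Missing and invalid
recordings are planted per (subject, visit, condition): missing conditions
are logged as absent, invalid ones get their span corrupted with dense
large artifacts so the pipeline's own quality control rejects them
(masked fraction ceiling 0.5). Movement sub-block pain ratings are
generated as manipulation-check fields only and are not consumed by the
numeric pipeline.

What the generator does *not* emulate: optode-scalp coupling and photon
transport, superficial/systemic physiology distinct from the cortical
signal (no short-separation channels exist in this montage), HbR-specific
neural effects, serially correlated GLM residuals beyond the planted
oscillations, and non-Gaussian behavioral distributions. Passing recovery
tests therefore demonstrates the pipeline's correctness and calibration
under its own assumptions, not robustness to every property of real
recordings.

## Statistical calibration and verification scale

Verification runs are sized to be decisive but cheap: noise-free beta
recovery uses 2 full-length recordings; coactivation-ordering recovery
uses 12 noisy seeds; null false-discovery calibration uses 1000 replicate
cohorts of n=10 drawn at the truth level (per-subject betas and behavioral
scores without raw-signal synthesis — the statistical structure is
identical and the raw-signal path is covered by the recovery tests); the
power check uses 1500 replicates. Under the global null, the per-family
probability of any BH q < .05 discovery is compared against
5% + 2√(.05·.95/R); the planted-effect check (a 1 within-subject-SD
change at n=10, analytic paired-t power ≈ 0.803) is compared against
80% − 2√(.8·.2/R), the same Monte-Carlo margin convention. A planted
brain–behavior correlation of 0.9 at n=200 must return within ±0.05
(Fisher SE at that n is ≈ 0.014 on the r scale, so the band is ~3.5 SE
plus clipping attenuation).

## Known limitations

- The 0.01 Hz high-pass makes single long blocks (the 6-minute VR
  conditions) poorly identifiable in the GLM under in-band physiological
  noise; per-subject VR betas are noisy even though noiseless recovery is
  exact. The windowed Cohen-d metric averages in-band noise over the
  6-minute span and is the better-powered per-subject measure for those
  conditions — consistent with its role as the primary activation-change
  metric.
- Group inference at n=10 has adequate power only for large effects;
  the pipeline reports both p and q and leaves reconciliation of
  borderline findings to the reader.
- The SNIRF reader is a minimal continuous-wave mapper (amplitude,
  wavelengths, stim blocks, optional age tag), not a full implementation
  of the format.
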