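# Methods

This note documents the models, parameters and numerical choices behind
`vaparc`, in the spirit of a package methods appendix. Nothing here reports
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Stimulus synthesis

**Original tokens** are 500 ms mono waveforms at 16 kHz. Voice tokens are
harmonic complexes with a time-varying F0 (default range 100–300 Hz: a base
frequency with slow drift and 3–7 Hz vibrato), a two-resonance ("formant")
spectral envelope (F1 ∈ [300, 900] Hz, F2 ∈ [1000, 2500] Hz), 1–3
syllable-like amplitude bursts and −40 dB breath noise. Nonvoice tokens
cycle through band-passed noise bursts, pure tones (300–3000 Hz),
logarithmic chirps and click trains (20–100 Hz). All tokens are finalized:
5 ms raised-cosine onset/offset ramps, then scaled to a common RMS.
Because "70 dB SPL" has no absolute digital meaning, the package defines the
reference **RMS 0.05 full scale ↔ 70 dB**; other levels scale linearly
(20 dB per amplitude decade). The level is set after ramping, so finalized
RMS values are exact and re-finalization is RMS-idempotent.

**Acoustic equivalents.** Each AE keeps its source's duration, sample rate,
voice/nonvoice category and provenance id.

* `e_s` (envelope/spectrum): the Hilbert amplitude envelope multiplied into
  white noise, plus white noise whose one-sided Fourier magnitudes are
  replaced by the original's magnitude spectrum (noise phases kept). The DC
  magnitude is replaced along with every other bin, keeping only its sign
  from the noise: a raw Gaussian DC draw has standard deviation √N and would
  otherwise dominate the spectrum norm. Components are mixed at equal RMS.
* `scr` (scrambled): the signal is split into 8 log-spaced bands using
  complementary raised-cosine masks that sum to one (so recombination is
  exact); within each band, 25 ms segments with 50% overlap and Hann
  cross-fades are permuted within 250 ms local windows; overlap-add output
  is renormalized by the window sum, so the identity permutation reproduces
  the input exactly. Segment/window/band counts are package defaults, not
  published values.
* `p_a` (pitch/amplitude): the frame-wise F0 contour (see §2) with unvoiced
  gaps linearly interpolated — the adopted reading of a "rectified" contour —
  rendered as a sinusoid by phase accumulation; white noise carries the
  original's 10 ms-smoothed intensity envelope. The sinusoid carries the
  same envelope, so the mixture preserves the original's amplitude dynamics
  as a whole; the two are summed at equal RMS. With no voiced frames the
  token falls back to the noise component and carries a warning flag.
* `rip` (ripple): dynamic moving ripples — 64 log-spaced carriers whose
  envelope is 1 + depth·sin(2π(velocity·t + density·octave) + φ) — sampled
  log-uniformly with velocity 1–30 Hz, density 0.25–4 cyc/oct, depth
  0.2–1.0 (package defaults; the source description gives none). Matching
  uses 6 features: mean and SD of jitter, shimmer and spectral flux.
* `tsp` (texture): Gaussian-process sound textures on a 30-band × 10 ms
  grid with separable exponential correlations, temporal length in seconds
  and spectral length in octaves, both log-uniform in [0.01, 2]; the field
  drives per-band dB envelopes (SD 10 dB) on band-passed noise. Matching
  uses 2 features: mean and SD of the HNR contour.

**Pool matching** z-scores features over the pool *plus the probe* (making
distances scale-free), takes the Euclidean argmin, breaks ties by lowest
member index, and relabels the selected waveform with the probe's category
and source id. Pools default to hundreds of members in tests and the
acceptance run; the procedure is size-agnostic and the matching rule is
verified against exhaustive enumeration.

## 2. Acoustic features and the sound SVM

Frame-wise analysis uses 40 ms Hann frames with 10 ms hop. F0 and HNR come
from the window-corrected normalized autocorrelation: the highest peak in
the lag range for 75–500 Hz (parabolic interpolation) gives the period;
HNR = 10·log10(r/(1−r)) with the peak value r clipped to [1e−4, 1−1e−4]
(≈ ±40 dB ceiling); frames are voiced when r ≥ 0.45. Jitter and shimmer are
frame-level proxies: relative changes of period and of frame RMS between
consecutive voiced frames. Spectral flux is the L2 change of the
L2-normalized magnitude spectrum.

The 88-slot feature vector (ordering in
`vaparc.acoustic_features.FEATURE_NAMES`) covers F0 statistics and voiced
fraction (8), HNR (4), jitter/shimmer (4), flux (3), spectral moments and
shape (16), 8 log-band energies (16), 13 cepstral coefficients from 26
log-spaced bands (26) and envelope/modulation/ZCR statistics (11).
Descriptors undefined for a token (e.g. jitter with < 2 voiced frames) are
imputed as 0. The slot set is this package's documented definition — the
claims downstream depend on relative, not absolute, accuracies, so no
attempt is made to replicate any external toolbox bit-for-bit.

Sound classification uses an SVM with a third-order polynomial kernel
(C = 1, features z-scored) under stratified k-fold cross-validation, or a
single fit on the originals tested on an AE set (cross-classification).

## 3. Experiment schedule and design matrix

Each run holds 12 mini-blocks (one per condition: 6 sound sets × 2
categories) of 9 sounds; sound onsets are spaced 0.5 s (sound) +
U(0.8, 1.2) s (silence); blocks sit in fixed slots of mean block length
(12.5 s) + 15 s gap, giving a deterministic 315 s run — which equals 197
volumes at TR 1.6 s. Block order is randomized per run; 24 of the 96 blocks
contain one immediate sound repetition and a button press at block end.
Because block slots are fixed, the inter-block silence varies by ±0.4 s
around 15 s while run length stays exact.

Task regressors are the 12 block boxcars plus the button press (13 columns),
convolved with a canonical two-gamma HRF (peak 6 s, undershoot 16 s, ratio
6, unit sum; cross-checked against nilearn's implementation) on a 0.1 s
grid and sampled at the TR. Nuisance columns: 6 motion parameters (caller
supplied) and 18 RETROICOR columns — sine/cosine Fourier expansions of
cardiac phase (order 3), respiratory phase (order 4) and the sum/difference
phases (order 1). Fitting is voxel-wise OLS with an explicit rank check
that names offending columns.

## 4. The synthetic cohort

The default study is 25 subjects × 8 runs on a 20×20×12 grid of 2.75 mm
isotropic voxels, hemispheres split at the first-axis midplane. Ground
truth plants one quasi-spherical blob per class per hemisphere (core 5%,
acoustic 5%, accessory 8% of the grid by default; placement is randomized
with non-overlap constraints and restarts). Per-run, per-condition betas
are class mean + i.i.d. Gaussian noise (SD 0.35 by default; effect size 1).

Class means per unit effect:

| class     | orig voice | e_s voice | scr voice | all other conditions |
|-----------|-----------:|----------:|----------:|---------------------:|
| core      | 1          | 0         | 0         | 0 |
| acoustic  | 0.55 ± p   | 0.50 ± p  | 0.50 ± p  | 0 (nonvoice: ∓p) |
| accessory | 1/3        | 1/6·h_s   | 1/6·h_s   | 0 |

* The acoustic field's **amplitude effect is shared** across originals and
  `e_s`/`scr`, which keeps it inside the univariate voice area while the
  e_s/scr interaction contrasts cancel — so it cannot enter the core
  conjunction. The small original-only margin (0.55 vs 0.50) mirrors the
  expectation that original sounds drive the field at least as strongly as
  any equivalent and keeps the AE contrast maps strictly nested inside the
  VA rather than sitting on the significance threshold.
* The **multivoxel pattern** (±p, p = 0.1 per unit effect, checkerboard
  sign so it sums to ≈ 0 in any searchlight-sized neighborhood) is added to
  voice and subtracted from nonvoice for {orig, e_s, scr}. Its support is
  the morphological **erosion of the acoustic field by the searchlight
  ball**: a searchlight map can localize information only up to its radius,
  so with support = erosion(labeled field) the set of centers with access
  to the field's information equals the labeled field — making voxel-level
  recovery scores meaningful rather than systematically dilated.
* **Between-subject variability** is a multiplicative gain per subject and
  class, calibrated so the subject-level SD of each class's peak response is
  an absolute 0.2 × effect. Calibrating to an absolute SD (rather than 20%
  of each class's own mean) makes Cohen's d proportional to the class mean —
  d ≈ 5 in core, ≈ 2.75 in acoustic, ≈ 1.7 in accessory — reproducing the
  core-largest effect-size profile.
* The accessory field's weak `e_s`/`scr` response has its own subject gain
  1 + N(0, 3): the group mean stays at effect/6 (so the interaction
  contrast with e_s/scr stays small and accessory is excluded from the core
  conjunction), but the sign is inconsistent across subjects, so group-level
  cross-decoding of that offset stays at chance. This operationalizes
  "weak, nonspecific AE responsiveness" — a *consistent* AE offset of any
  detectable size would be decodable by construction at n = 25 and would
  make an accessory field logically impossible.

BOLD simulation (per run) multiplies the design matrix into the betas,
optionally adds the 18 RETROICOR confounds with random per-voxel amplitudes,
plus white noise; with zero noise the GLM recovers betas to numerical
precision.

## 5. Group inference and the parcellation

The published factorial-with-pooled-error machinery is replaced by per-voxel
one-sample t-tests over subjects on contrast values (one-sided, positive),
with Bonferroni FWE (default α 0.05 over the analysis mask — here the whole
grid) or Benjamini–Hochberg FDR. Conjunction uses the minimum-statistic
rule (significant in every component map), which equals mask intersection.

Searchlight decoding uses a 5 mm sphere (the 3³ voxel cube at 2.75 mm), a
linear SVM with C = 1 and no intercept, solved by dual coordinate descent
on the hinge-loss dual in kernel form (numba-compiled; ~10⁶ fits per cohort
run in seconds). Features are standardized per fold with training-set mean
and SD (SD 0 → 1), which makes accuracies invariant to voxel-wise affine
rescalings applied equally to train and test. scikit-learn's SVC is the
independent cross-check in the test suite. Cross-classification fits once
on all original-sound runs (16 balanced patterns) and tests on the 16
patterns of one AE set; within-set decoding is leave-one-run-out.
Group accuracy maps are one-sample t vs. chance 0.5; ceiling voxels with
zero between-subject SD get t clipped to ±100 so averaged maps stay finite.
The five cross-classification t-maps are averaged voxel-wise and the
average is thresholded at the single-map t quantile (uncorrected p < 0.001
by default) — conservative, since the null SD of a 5-map average is
≈ 1/√5.

Masks: **original VA** = FWE mask of [ORIGvoice > ORIGnonvoice];
**core VA** = conjunction of the five interaction maps ∩ original VA;
**acoustic VA** = averaged-cross mask ∩ original VA ∖ core (core wins on
overlap — the published subfields are disjoint but state no rule, and the
published accessory percentages are inconsistent with the printed counts,
so this implementation enforces the explicit disjoint partition);
**accessory VA** = the remainder. Coverage percentages are
100 × count / n_original per hemisphere, rounded half-up to one decimal;
voxels on the hemisphere split plane count as right (index ≥ midplane),
i.e. the split plane belongs to the right half-grid.

**Smoothing.** Paper-style maps use an 8 mm FWHM Gaussian (4 mm replication
mode) applied to subject-level contrast or accuracy images. The recovery
pipeline defaults to **no smoothing**: on a 20×20×12 grid with compact
ground-truth blobs, smoothing leaks scaled signal (mean and subject SD
shrink together, so t stays large) 2–4 voxels past every boundary and
degrades voxel-level Jaccard for purely geometric reasons. This is a
scoring-fidelity choice, not a claim that unsmoothed analysis is superior
on real data.

**Voice selectivity.** Per subject and voxel, every condition is scaled as
(β_c − β_ORIGnonvoice)/(β_ORIGvoice − β_ORIGnonvoice); the anchors are
exact (nonvoice → 0, voice → 1) and the scaling is affine invariant. A
voxel is voice-selective iff all 10 AE conditions stay strictly below 1/3
(strict inequality adopted; the source does not say). Zero-denominator
voxels are excluded from the group sum and counted.

**Functional patches.** Per subject, the top-10 local maxima
(26-connectivity, ties by first index) of the statistic inside the group
mask are candidates; each patch takes the candidate nearest its reference
coordinate; patches with no candidate, or pairs of chosen centers closer
than 10 mm, fall back to their reference coordinates, and every fallback is
logged. ROIs are 5 mm spheres. The anatomical "atlas" is a generated toy
label volume (five slabs per hemisphere named after auditory subregions —
synthetic stand-ins with no anatomical claim); real NIfTI label volumes can
be supplied instead.

## 6. Problem sizes and runtime

The acceptance run uses the full default study (25 subjects, 8 runs,
20×20×12 grid; ~12 s for the complete pipeline on one CPU), 20-seed
permutation-null batches on an 8×8×6 grid with 10 subjects and 4 runs, a
140-token sound set for the acoustic SVM, and pools of 100–300 members for
matching oracles. These sizes were chosen to keep the whole suite
desk-scale while leaving all statistical margins intact.

## 7. Known limitations

* The voxel noise is white in space and time; no AR structure, motion,
  distortion or physiological nuisance beyond the simulated RETROICOR
  columns.
* The synthetic sound classes are caricatures: real voice/nonvoice corpora
  have far more within-class acoustic diversity, so the acoustic SVM's
  near-perfect accuracy here says nothing about real-world accuracy.
* The 88-feature set and the scramble/ripple/texture parameter defaults are
  package definitions, not published values.
* Effect amplitudes per condition are free parameters chosen to reproduce
  the qualitative subfield structure (core ≫ others in d; acoustic field
  decodable and inside the VA; accessory weak and inconsistent), not any
  particular published effect size.
* Recovery scores are exact because the generator satisfies the analysis
  assumptions by construction; they measure pipeline correctness, not
  biological truth.
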