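# Methods

## Overview

`mpcad` detects and localises tumours in co-registered multi-parametric MRI
(MP-MRI) of the prostate in three stages operating at two spatial scales:

1. **RD-STD** (voxel resolution): statistical textural distinctiveness
   proposes candidate regions with high sensitivity.
2. **RD-FM** (region resolution): a 242-entry radiomics feature vector per
   candidate, two-stage feature selection and an SVM prune false positives.
3. **rADC-CRF** (voxel resolution): a conditional random field driven by
   relative-ADC texture refines the surviving detections.

All evaluation is leave-one-patient-out (LOPO): nothing fitted on a
patient's own data — feature standardisation, PCA loadings, EM mixture, mRMR
ranking, classifier weights — is used to score that patient.

## Imaging models

The DWI stack at b = 0, 100, 400, 1000 s/mm² follows the mono-exponential
decay S = S₀·e^(−bD).  Per voxel, D (the ADC) and ln S₀ come from ordinary
least squares of ln S on b, with a signal floor ε = 10⁻⁶ before logarithms;
voxels below the floor at every b-value are flagged and set to D = 0.

* **CHB-DWI** extrapolates the fitted decay to a target b (default
  2000 s/mm²); an optional ridge weight shrinks D towards zero (a Gaussian
  prior on the slope), with point estimate identical to plain least squares
  in the noiseless limit.  The default ridge is 0.
* **CDI** mixes the cross-b-value signal product over a local subvolume with
  a normalised isotropic Gaussian kernel (default physical radius 2 mm).
  The joint signal density that the original formulation integrates over is
  not identifiable from the data we model, so deterministic Gaussian mixing
  realises the same "local signal mixing" structure; radius 0 degenerates to
  the plain per-voxel product.
* **Relative ADC** normalises each candidate ROI (and its disk-dilated
  neighbourhood, SE radius 3 voxels in-plane) by the median ADC of the
  dilated surround, then divides the rest of the map by the mean of those
  surround medians.  Overlapping dilated ROIs are resolved by
  nearest-centroid ownership.  ROIs whose surround median is zero are
  skipped with a warning.  With no candidate ROIs the map is normalised by
  the gland median — used only when the phantom has no lesion.  The map is
  invariant to global rescaling of the ADC volume by construction, which is
  exactly why it corrects inter-patient ADC variation.

## Voxel feature bank (96 columns)

Per axial slice and per in-mask voxel: 4 first-order window statistics
(mean, population SD, Fisher kurtosis, skewness — both defined as 0 for
zero-variance windows), 72 co-occurrence statistics (18 statistics × 4
offsets at 0°/45°/90°/135°, window quantised to 32 levels by its own
min–max, symmetric and normalised), 12 Gabor magnitudes (wavelengths 3/6/12
px × 4 orientations, kernels made zero-mean so a constant offset produces no
response), and 8 Kirsch compass responses.  Windows are 5×5 and clipped at
image borders; degenerate (single-gray-level) windows give the fallbacks
energy 1, contrast 0, entropy 0, correlation 0.

Each operator group reads one configured channel (first-order and
co-occurrence on ADC, Gabor on T2w, Kirsch on CHB-DWI by default), keeping
the bank at exactly 96 columns; the assignment is configuration-exposed
because the source texts are ambiguous about how the 96 features distribute
over the available channels.

The in-gland analysis mask is eroded in-plane by the window half-width
(2 voxels) before feature extraction.  Without this, windows centred on
gland-edge voxels mix extra-prostatic signal and form spuriously distinct
"edge" texture atoms that flood the candidate stage; eroding by the window
support removes the artefact at the cost of a thin unanalysed rim.

## RD-STD

The feature bank is z-scored and PCA-compacted to the smallest u components
reaching 90% cumulative explained variance.  A Gaussian mixture of m = 8
*texture atoms* is fitted by EM on the training patients' gland voxels
(k-means++ initialisation from the seed, covariance ridge 10⁻⁶, tolerance
10⁻⁶, ≤ 500 iterations; one re-seed on component collapse).  m is not
dictated by the problem; 8 is small relative to the voxel count while
leaving room for lesion, mimic and several background atoms.

Atom-pair distinctiveness is

    β_ij = log(|Σ_j|/|Σ_i|) − u + tr(Σ_j⁻¹ Σ_i) + ½ (μ_j−μ_i)ᵀ Σ_j⁻¹ (μ_j−μ_i)

with only the Mahalanobis term halved, implemented exactly in this form.

Saliency combines β with the atom occurrence probabilities P(t|Z) measured
on the held-out patient (mean EM responsibility).  Two variants are
provided: the self-indexed form α_i = P(t_i|Z)·Σ_j β_ij, and the
cross-indexed form α_i = Σ_j β_ij·P(t_j|Z).  The self-indexed form weights
an atom's distinctiveness by its own abundance, so a rare suspicious texture
can never dominate in a healthy-dominated gland; the cross-indexed form
scores an atom by how distinct it is from the *commonly occurring* textures,
which is the behaviour a saliency detector needs and matches the textural
distinctiveness literature this construction descends from.  The function
default is the self-indexed form; the pipeline configuration default is the
cross-indexed variant (`rd_std.saliency_prob_index: "j"`).

Voxels are assigned to their maximum-responsibility atom; atoms with
α > α_max/2 (strict) are salient and their voxels become detections, grouped
into per-slice 8-connected candidate regions of at least 6 voxels.

## RD-FM

Each candidate region yields 242 named features:

* Morphology (3, mask only): f₁ = (A_closed − A_opened)/A_initial with a
  disk SE (radius 2); f₂ = |P_initial − P_reconstructed|/P_initial after
  keeping the 8 lowest Fourier harmonics of the boundary (resampled to 128
  equidistant points, then lightly smoothed with a 5-point circular moving
  average to suppress marching-squares staircase ripple, which is
  quantisation noise rather than shape); f₃ = |A_low ⊕ A_high| / |A_low ∪
  A_high| between the filled reconstructions at 2 and 16 harmonics.
* Asymmetry (4, mask only): the region is split through its centroid along
  the major or minor principal axis (second central moments); each split
  gives (A_large − A_small) normalised by the whole area or by the smaller
  half (capped at 10 when a half is empty).  Voxels within 10⁻⁹ of the
  split line belong to neither half, so symmetric discrete shapes score 0.
* Size (1): area × in-plane voxel area (mm²).
* Physiology (26 × 9 channels): 7 first-order statistics of the in-region
  intensities plus 19 statistics of one *global* horizontal-offset
  co-occurrence matrix counting only pixel pairs with both pixels inside the
  region (32 levels, min–max over the region).  The 19th statistic is the
  entropy normalised by its maximum log₂(L²).

Channels are keyed by name (T2w, ADC, rADC, CHB-DWI, CDI, b0, b100, b400,
b1000), so assembly is independent of input order.  The relative-ADC channel
used here is recomputed from the stage-1 candidates of the same patient.

Training labels: a region is positive iff ≥ 50% of its area overlaps the
truth mask (configurable).

Feature selection is two-stage.  Stage 1 ranks each channel's 26 physiology
features (and the pooled 8 morphology/asymmetry/size features) by greedy
mRMR — mutual information on equal-frequency-discretised features (10 bins,
reduced automatically when samples are few; low-cardinality columns keep
their values) — then grid-searches the ranked-prefix size that maximises the
chosen criterion (sensitivity, specificity or AUC) of an SVM under grouped
CV over the training patients (3 folds).  Stage 2 pools the survivors and
repeats ranking plus grid search.  The same training folds serve both
stages; no nested CV (documented choice — the alternative is much costlier
and the selection consumer is the same classifier).

The classifier is an RBF-kernel SVM (C = 1, γ = 1/d) on features z-scored
with training statistics.  Class weights are balanced because candidate sets
are heavily imbalanced (few true tumour regions among many false
positives).  A training fold whose regions are single-class raises an
error at the function level; the pipeline catches it and labels every test
region with that single class, so one degenerate fold cannot abort a study.

## rADC-CRF

Labels Y over the analysis mask minimise

    E(Y) = Σ_i ψ_u(y_i) + Σ_(i,j)∈C w · exp(−‖f_i−f_j‖²/(2σ²)) · |y_i − y_j|

with 4-neighbour in-plane cliques C.  Unary costs come from the region
classifier: scores are squashed to probabilities by the logistic function
(background voxels get p = 0.01) and ψ_u(1) = −log p, ψ_u(0) = −log(1−p),
clamped at 10⁶.  The pairwise features f are the 96-column texture bank
evaluated with every operator group on the relative-ADC channel, PCA-compacted
to 90% variance; σ defaults to the median pairwise feature distance and
w = 1.

The binary field is relaxed to [0, 1]; |Δy| is smoothed as √(Δy² + 10⁻⁴),
making the objective convex and well-conditioned (curvature of the smoothed
kink scales as ε^(−1/2); the larger ε keeps projected gradient descent
stable at useful step sizes, and the rounding step below uses exact
energies so the smoothing bias does not reach the result).  Descent halves
the step whenever energy would increase and re-grows it by 1.2× after each
accepted step, so the recorded energy trace is non-increasing.  The binary
solution is recovered by scanning the level sets of the relaxed minimiser
(0.5 always included) and keeping the cut with the lowest exact energy —
for total-variation energies with submodular pairwise terms some level set
of the continuous minimiser is a global binary optimum, which a fixed 0.5
threshold does not guarantee.

A positive region survives refinement iff part of its mask remains in the
refined field; its mask shrinks to that intersection.  Refinement therefore
never adds positive voxels.

## Phantom cohort

The generator emulates the structure of a clinical MP-MRI exam, not its
anatomy: an ellipsoidal gland (radii 13×10×3 voxels in a 40×40×8 volume at
1.5×1.5×3 mm), DWI channels synthesised from the decay law with a tissue
diffusivity map, T2w with lesion hypo-intensity, and Rician magnitude noise
(σ = 15 against S₀ ≈ 800, i.e. SNR ≈ 50 at b = 0 falling to ≈ 10 at
b = 1000).  Blobs are axis-aligned ellipsoids with a 2-voxel Gaussian
boundary blend, giving an analytic core and a realistic partial-volume rim.

Default tissue values: background D = 1.6×10⁻³ mm²/s (with ±8% per-patient
jitter emulating the inter-patient ADC variation the relative-ADC channel
corrects), tumours D = 0.7×10⁻³ with T2w contrast 0.55, and two benign
*mimics* per case at D = 0.85×10⁻³ with normal-to-bright T2w (contrast
1.05).  Mimics are deliberately ADC-dark enough to be proposed by the
saliency stage — they play the role of the false-positive candidates that
dominate clinical voxel-stage output and give the region classifier genuine
two-class training data; their T2w appearance is what separates them from
tumours.  The reference cohort is 10 cases, every second one carrying one
tumour.

What the phantom does **not** model: zonal anatomy, bias fields, geometric
distortion, registration error between channels, histology-defined lesion
grade, or lesion shapes beyond smooth ellipsoids.  Passing the end-to-end
suite therefore demonstrates that the pipeline machinery recovers known
structure under its own generative assumptions — not clinical performance.

## Evaluation protocol

Region level: a positive region is a true positive iff ≥ 50% of its area
overlaps the truth mask (strict threshold); otherwise a false positive.
Negative regions are true negatives unless they meet the overlap threshold
(false negatives).  A tumour — one 3-D connected truth component — touched
by no positive region adds one false negative: a missed tumour counts once,
not once per slice it spans.  Proportions carry 95% Wilson intervals.

Lesion-level detection sensitivity is the fraction of tumours overlapped by
at least one positive region.  Patient level: a patient is called positive
iff at least k (default 1) final regions are positive.

At stage 1 every candidate is a detection, so stage-1 specificity is 0 by
construction and only its sensitivity is meaningful — matching the
sensitivity-first design intent of the candidate stage.

## Problem sizes and determinism

The reference study (10 patients, ≈ 1 300 analysed gland voxels each after
rim erosion, ≈ 60–70 candidate regions cohort-wide) runs in a few minutes on
one CPU; all randomness (phantom noise, EM initialisation) derives from a
single integer seed, and repeated runs are bit-identical.

## Known limitations

* The CDI mixing kernel and the CHB-DWI ridge are documented stand-ins for
  under-determined formulations; both default to their simplest member.
* Stage-1 candidates inherit the texture-atom granularity: a lesion
  bordering a texturally similar structure can merge into one candidate,
  diluting its overlap label.
* The thin partial-volume rim of a lesion (blend region) is often excluded
  from candidates; per-slice cap sections of a tumour may be missed even
  when the tumour itself is detected.
* The CLI covers simulation, channel derivation and the LOPO study
  (`simulate`, `derive`, `study`); training and applying a frozen model to
  new cases goes through the library (`MPCaDModel`, `run_mpcad`).
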