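# Methods

This note documents the models, parameter choices and numerical
conventions behind `histo3c`, and what the synthetic benchmark does and
does not demonstrate.

## Channel handling

Images are 8-bit RGB arrays in row-major (row, col) order; sizes are
quoted width×height in prose (a "700×460" image is a `(460, 700, 3)`
array). Grayscale conversion uses ITU-R BT.601 luma weights
(0.299, 0.587, 0.114), rounded back to 8 bits; the weights are an
argument of `to_gray` for anyone who needs BT.709 or flat weights. No
resizing, stain normalization or other preprocessing is applied before
feature extraction.

## Co-occurrence features (GLCM1 / GLCM4)

The co-occurrence matrix is computed at all 256 gray levels (intensities
used as-is), offset distance 1, symmetrized (each ordered pair counted
both ways, making 0° ≡ 180°) and normalized to probabilities. Angles
follow the (sin θ, cos θ)·d offset convention. The 22 statistics are the
classical Haralick set plus the Soh–Tsatsoulis and Clausi extensions,
in a fixed documented order (`HARALICK_NAMES`). Conventions that the
literature leaves open and we fix:

* entropy-type features use log base 2 with 0·log 0 = 0;
* the two homogeneity variants are Σp/(1+|i−j|) and Σp/(1+(i−j)²); the
  "inverse difference (moment)" pair are the normalized variants
  Σp/(1+|i−j|/N) and Σp/(1+(i−j)²/N²), N = 256;
* sum variance is Haralick's published formula (second moment of
  p_{x+y} about the sum entropy);
* correlation is defined as 0 when a marginal is degenerate (constant
  channel), keeping every feature finite; IMC2's radicand is clamped at
  0.

GLCM4 concatenates the four per-direction 22-vectors (0°, 45°, 90°,
135°) rather than averaging them, giving the 88-dimensional per-channel
descriptor.

## APVEC, Hu moments, wavelet energies

APVEC is the plain per-channel mean. The seven Hu invariants are built
from second/third-order normalized central moments of the channel
treated as a mass distribution; because the raw values span ~30 orders
of magnitude they are reported as sign(h)·log₁₀(|h|+1e−30) by default
(raw values via `log_scale=False`) so that one min–max scaling can
serve all descriptors. Note the seventh invariant is a *skew*
invariant: proper rotations preserve it, mirror reflections flip its
sign.

Wavelet energies use a coif5 decomposition of depth 5; for each level
(finest→coarsest) the energy is the summed squares of the three detail
subbands — summing the orientations keeps the descriptor at one value
per level. The boundary mode defaults to `periodization`: it is the
only mode under which the orthonormal transform exactly partitions the
input energy between subbands (verified to 1e−6 relative on dyadic
sizes), which makes the energies interpretable as an energy
distribution across scales; `mode` is an argument for anyone preferring
symmetric extension.

## LBP and CLBP

The binary-pattern operator is the original 3×3-window definition: the
eight *physical* neighbors (no circular interpolation), ordered
counter-clockwise from the east neighbor, thresholded with s(x)=1 iff
x ≥ 0; border pixels are skipped rather than padded. CLBP splits the
local differences into the sign component S (identical to LBP) and the
magnitude component M, which thresholds |g_p − g_c| against its global
mean over all interior pixels of the channel. Both code maps are
collapsed through the rotation-invariant uniform (riu2) mapping —
uniform codes to their popcount, all others to one bin, P+2 = 10 bins —
and the two normalized histograms concatenated (S then M) give the
20-dimensional descriptor. The center component C (center intensity vs
its global mean) is computed and exposed but kept out of the default
vector so the descriptor's printed dimension stays 20.

## Tamura statistics

Tamura's six perceptual statistics are reported in the order
coarseness, contrast, directionality, line-likeness, regularity,
roughness (= coarseness + contrast). His definitions leave several
parameters open; we fix: coarseness windows 2^k, k = 1..5; contrast
σ/α₄^¼; directionality from a 16-bin orientation histogram (Prewitt
gradients, votes gated at the 12th magnitude percentile) scored as one
minus the normalized circular spread about the dominant peak;
line-likeness as the cosine-weighted co-occurrence of direction bins at
a 4-pixel shift; regularity as 1 − 0.25·Σ of the coefficient of
variation of the other four statistics over a 4×4 subimage grid. These
are conventional readings, fixed for reproducibility and exposed as
module constants.

## Gabor bank and HOG

The Gabor bank holds 5 scales × 8 orientations of complex kernels on a
fixed 39×39 support. Center frequencies descend geometrically from
0.25 cycles/pixel by √2; orientations are kπ/8; the Gaussian envelope
is isotropic with σ ≈ 0.56λ (one-octave bandwidth). Responses are
magnitudes of the complex convolution; pooling is the mean over a
non-overlapping grid of 46-row × 70-column blocks (images are
center-cropped to the largest fitting grid — on 700×460 exactly 10×10
blocks), ordered (scale, orientation, block row, block col): 4000
values per channel. There is no internal normalization, so the
descriptor is linear in input amplitude.

HOG uses central-difference gradients, unsigned orientations on
[0°, 180°), a 4×8 grid of cells, per-cell 9-bin magnitude-weighted
histograms with linear interpolation between adjacent bins, and a
single global L2 normalization (zero stays zero): 288 values per
channel. The common overlapping-block normalization scheme is
deliberately absent — no standard small parameterization of it produces
a 288-dimensional vector.

## Fusion and classification

Three-channel fusion concatenates per-channel vectors in R, G, B order;
cross-descriptor fusion is plain cascade concatenation, no reweighting.
The classifier is an RBF-kernel SVM with c = 2 and γ = 1 on features
min–max scaled to [0, 1]; the scaler is fit on training rows only.
Scaling is on by default (an RBF with γ = 1 on raw Haralick magnitudes
is degenerate — every kernel entry collapses) and can be switched off.
Splits are drawn per patient, stratified by class, with at least one
train and one test patient per class; each of the five trials redraws
the split with seed `seed + t`. Patient-level accuracy is the literal
mean of per-patient correct fractions (no majority vote). Metrics with
zero denominators are reported as missing, never as 0. Rows are sorted
by image id before fitting, so reports are bit-reproducible given the
seed.

## Synthetic data model

The generator emulates the *structure* of an H&E archive, not tissue
morphology: a pink background plus elliptical blue-purple nucleus
blobs, rendered per image with seeded per-patient offsets (stain tint
sd 3, density log-sd 0.15, size log-sd 0.08) so images within a patient
are correlated and patient-disjoint splitting is actually load-bearing.
Class differences are controlled by two knobs:

* `class_effect` t: malignant images get denser (×(1+0.25·t_lum)),
  smaller (×(1−0.15·t_lum)) and more opaque nuclei, benign the
  opposite, where t_lum = t/(1+chroma_effect);
* `chroma_effect`: adds a class-signed color shift of magnitude
  1.2·t·chroma_effect along (1, −0.299/0.587, 0) — a direction with
  exactly zero BT.601 luma — to the nucleus color (40 % of it to the
  background), while shrinking the structural effect above.

At t = 0 both classes are drawn from the same distribution regardless
of the other knobs. Magnification ("40X"…"400X") is a pure blob-size
scale factor {0.6, 1.0, 1.5, 2.4}. Defaults are desk scale: 6 benign +
14 malignant patients (echoing the real-world ~1:2.4 class imbalance),
10 images per patient, 700×460 pixels, one magnification (200X),
noise sd 8, class_effect 3, chroma_effect 1.

What passing tests show: the pipeline recovers a planted class signal
of realistic geometry under a leakage-free protocol, and the
three-channel representation retains hue-borne signal that grayscale
provably discards (the luma-orthogonal shift is invisible to `to_gray`
by construction). What they do not show: performance on real tissue —
real H&E images have structured backgrounds, stain variability
correlated with scanners, and subclass morphology none of which the
blob model attempts.

## Known limitations

* Under the high-chroma configuration, grayscale *texture* descriptors
  (GLCM) keep a residual structural signal (the luminance effect
  shrinks by 1/(1+chroma_effect) but is not zero), so the
  three-channel-vs-gray gap is large and stable for the color-borne
  APVEC descriptor (≈30+ points) but small and seed-dependent for
  GLCM. This mirrors the fact that chroma loss harms color features
  more than pure texture features.
* Tamura's regularity and line-likeness have no canonical published
  parameterization; values are comparable within this package, not
  across implementations.
* The 3×3 LBP/CLBP operator is implemented for P = 8, R = 1 only (the
  configuration the descriptors are defined with); other (P, R) would
  require circular interpolated sampling.
* Five-level wavelet decomposition of a 460-pixel dimension with coif5
  exceeds the boundary-effect-free depth; the coarsest levels are
  boundary-dominated but deterministic, and the descriptor is used
  comparatively.
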