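# Methods

This note documents the models and procedures implemented in `imageprops`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the verbal
definitions of the properties leave room.

## Image handling

Images are RGB arrays in [0, 1] (`RasterImage`); grayscale conversion uses
ITU-R BT.601 luma weights (0.299, 0.587, 0.114). Reference implementations
of these properties used various toolchains for grayscale conversion, so
absolute spectral *levels* can shift slightly between implementations;
spectral *slopes* are unaffected. All properties are computed at native
resolution except self-similarity, whose definition includes a reduction to
~100,000 pixels (bilinear, anti-aliased, aspect-preserving, no upsampling).

## Color

Mean H, S, V over all pixels after hexcone RGB→HSV conversion (H scaled to
[0, 1]). Hue is averaged **arithmetically**, with the discontinuity at red,
matching the plain channel-mean of common toolbox pipelines; a circular
mean is available (`circular_hue=True`) but is not the default. Achromatic
pixels carry H = 0 and are included in the hue mean.

## Fourier slope and sigma

The luminance image is padded to a square by centered mirror reflection
(zero padding would inject spurious high-frequency energy), Fourier
transformed without windowing (a Hann window is available as a sensitivity
flag), and |FFT|² is averaged over annuli of integer radius r = 1…N/2
cycles/image with the DC term excluded. Mean log₁₀ power is computed in 20
equal log₁₀-frequency bins over the fit range **[5, N/4] cycles/image**;
empty bins are skipped and at least 8 non-empty bins are required. A least
squares line through the bin means gives the slope; sigma is the sum of
squared bin residuals divided by the number of used bins. The fit range
excludes DC-adjacent bins (dominated by global layout) and the top octave
(pixel-level aliasing); the exact range and bin count of earlier
implementations are unpublished, so slopes are comparable in distribution,
not digit for digit.

## Edge map, edge density, orientation entropies

A bank of odd-symmetric Gabor kernels — 24 orientations over 0–180° at
wavelengths {4, 8, 16} px, one-octave bandwidth — is convolved with the
luminance image (FFT convolution with edge-replicated boundaries). Each
pixel keeps the maximal absolute response (magnitude) and a **signed**
orientation in [0, 360°): the winning filter's edge tangent, plus 180° when
the signed response is negative, so edge polarity is preserved. A border
margin of min(largest kernel radius, min(H, W)/8) pixels is excluded: there
the response reflects the boundary extrapolation, not image content, and
the stray orientations it produces measurably distort the entropies.

* Edge density = Σ magnitude / n_pixels × 1000. The ×1000 scale constant is
  a reporting convenience; absolute values are not comparable across
  implementations with different banks.
* First-order entropy = Shannon entropy (bits) of the magnitude-weighted
  orientation histogram with **B = 24** bins over 360°. 24 bins were chosen
  because reported first/second-order entropies on natural photographs
  reach ≈ 4.4 bits, which exceeds log₂ 16 = 4; B = 24 (maximum
  log₂ 24 ≈ 4.585) accommodates those values. Configurable.
* Second-order entropy: the n_top = 10,000 strongest edge elements
  (deterministic tie-break by row-major pixel order) are paired; for each
  distance annulus {(0,20], (20,40], (40,80], (80,160]} px a histogram of
  ordered pairwise orientation differences (mod 360°) is accumulated, and
  the result is the mean entropy over non-empty annuli (an error is raised
  only if every annulus has fewer than 100 pairs). The exact pair weighting
  of earlier implementations is unpublished; this definition satisfies the
  verbal contract — maximal for mutually unpredictable orientations, ~0 for
  a globally coherent orientation field — and is checked against an
  all-pairs brute-force oracle.

## Self-similarity (PHOG)

After reduction to ~100k pixels, signed gradient orientations (0–360°, from
the color channel with the maximal gradient magnitude per pixel, standard
PHOG practice) are binned into 16-bin magnitude-weighted histograms for the
whole image and for the 4/16/64 sub-rectangles of pyramid levels 1–3, each
normalized to sum 1. Self-similarity is the **median** (the convention of
the PHOG-derivative literature; mean available) of the histogram
intersections Σ min(h, g) between the 84 sub-histograms and the ground
histogram. Sub-rectangles with zero gradient energy are flagged and
skipped; a featureless ground level is an error.

## Symmetry and the Pa/Pf variances

Both are computed from a fixed deterministic bank of 48 analytic kernels:
12 orientations × {odd, even} Gabor pairs on luminance, plus 12 oriented
odd kernels on each color-opponent plane (R−G and B−(R+G)/2); wavelength
8 px, one-octave bandwidth. Responses are rectified and max-pooled into an
8×8 grid with mirror-symmetric cell boundaries. This bank stands in for the
first-layer features of a pretrained convolutional network: it keeps the
color/edge/texture coverage such features provide while removing a
model-weights dependency; absolute Pa/Pf scales are therefore
implementation-defined and only orderings are meaningful across
implementations.

* sym_lr = 1 − Σ|G − mirror(G)| / (Σ|G| + Σ|mirror(G)|), where mirror
  reverses grid columns and swaps each filter with its orientation-mirrored
  partner (index k → (12−k) mod 12 within each block of 12); sym_ud uses
  row reversal (same partner map). 1 = perfect mirror symmetry; a
  featureless image is defined as 1.0 with a warning.
* Pa, Pf: responses are normalized per cell to sum 1 over filters (cells
  with zero energy dropped); a_f is the cell average per filter. Pa is the
  population variance of a over filters (low Pa = many filters respond =
  richness); Pf is the mean over filters of the variance over cells
  (response variability across image sections).

## Classification

Images ranked by a rating term are split into terciles of floor(n/3); the
lowest and highest terciles form the binary task (ties broken by stable id
order; a labeling whose boundary values are shared by > 5% of items is
flagged tie-dominated). Stratified 10-fold cross-validation with seeded
shuffling: per fold, features are z-scored on training-fold statistics only
and an SVM-RBF is trained with C = 1 and kernel width 1/(d · Var_train)
(equivalently sklearn's `gamma='scale'` inside the scaling pipeline); these
hyperparameters are recorded in every report and overridable. Fold
accuracies yield the mean, a Student-t 95% CI, and a one-sample *t* against
the 50% chance rate with df = 9. Two runs are compared with a
pooled-variance two-sample *t* over the fold accuracies (df = 18).
Repeated cross-validation (`--repeats R`) averages R independent 10-fold
partitions; the default is a single run.

## Regression

OLS with intercept; adjusted R² = 1 − (1−R²)(n−1)/(n−p−1); standardized
βᵢ = bᵢ·sd(xᵢ)/sd(y) with matching standard errors; AIC in the
n·ln(RSS/n) + 2(p+1) convention (only differences matter, the constant is
recorded). Backward elimination removes, at each step, the predictor whose
removal most decreases AIC and stops when no removal decreases it; the
reduced model is refit and the path logged. Best-subset search enumerates
all C(p, k) subsets per size (guarded to p ≤ 20) and ranks by adjusted R²
(for fixed k this equals ranking by R²); the report carries a boolean
membership matrix per (size, rank) suitable for a shaded membership plot.
Coefficient p-values are reported unadjusted across the 13 predictors; the
CLI prints a multiplicity warning. Exact collinearity raises an error
naming the dependent columns.

Group comparisons use Kruskal–Wallis per feature with pairwise Wilcoxon
rank-sum post-hoc tests, Holm-corrected within each feature's family of
pairs; rating correlations use Spearman's r (average ranks for ties) with
two-sided p-values.

## Synthetic data

The generator emulates the *property ranges* of affective photograph
collections, not their content. Six recipe kinds span the feature space:

* `powerlaw_noise` — random-phase fields with amplitude ∝ f^(exponent/2)
  (exponents drawn from [−3.5, −1]), optionally tinted with a random
  hue/saturation to control the HSV means;
* `grating` — sinusoidal gratings with additive noise (strong orientation
  concentration, positive spectral slopes in the fit range);
* `tiled_texture` / `split_content` — high / low self-similarity;
* `mirrored_composite` — blend (1−w/2)·base + (w/2)·mirror, so w = 0 is
  the base and w = 1 the exactly symmetric average, making symmetry
  monotone in w (a full swap to the mirrored copy would merely reproduce
  the base's own asymmetry);
* `colored_field` — smooth hue fields with faint texture (no image is
  featureless).

Oriented textures superpose single-polarity odd-Gabor edge elements with
orientations drawn uniformly or from a von Mises distribution; the
single-orientation case is a pure linear intensity ramp, whose gradient has
one direction *and polarity* everywhere — a sinusoidal grating cannot
achieve this, since its rising and falling edges carry opposite polarities
(θ and θ+180°).

`gen_study` builds a mixed corpus cycling through the six kinds, extracts
the 13 properties, and generates ratings as an affine map onto the rating
scale of Σ βᵢ·zᵢ + ε, where z are the z-scored **measured** features —
so parameter-recovery tests are exact by construction and independent of
generator fidelity. With `target_r2` given, betas are rescaled so the
signal has that sample variance and ε gets variance 1 − target_r2; the
stored betas are then the true standardized coefficients. Corpus-scale
extraction uses n_top = 2000 for the second-order pair statistic (≈ 4·10⁶
ordered pairs per image, fully converged for the corpus statistics; the
pair loop is the dominant cost at the single-image default of 10,000).
All generators are deterministic given their seed (numpy PCG64).

What passing tests on synthetic data do **not** show: real affective
photographs have object content, correlated color/texture statistics and
photographic conventions that no recipe reproduces; absolute feature
means of real datasets are not matched, only attainable ranges and the
relative orderings the properties are defined to capture.

## Problem sizes used in the shipped checks

Chance calibration uses 600×13 standard-normal feature tables with 20
random balanced labelings; slope recovery uses 20 random-phase images at
256²; parameter recovery uses 1000 corpus images at 128² with
target r² = 0.3 and 100 rating-noise replicates (features extracted once).
These sizes make every check reproducible on a single CPU in minutes while
keeping Monte-Carlo error well inside the stated tolerances.

## Known limitations

* Absolute values of edge density, Pa/Pf and the entropies depend on bank
  parameters (documented defaults, all configurable, recorded in run
  manifests); comparisons are meaningful within a configuration only.
* The hue mean is non-circular by default; images with hue mass on both
  sides of red are best analyzed with `circular_hue=True`.
* Second-order entropy subsamples the strongest edge elements; on images
  with more than n_top active elements the statistic is an estimate (the
  all-pairs value is recovered exactly below n_top).
* The exhaustive subset search is limited to 20 predictors by design.
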