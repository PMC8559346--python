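# Methods

`glomclass` classifies single-glomerulus image patches from PAS-stained
kidney-biopsy sections as **sclerotic** or **non-sclerotic**. The
discrimination rests on two visual facts of glomerulosclerosis: the white
Bowman's space and capillary lumens shrink or disappear as extracellular
matrix fills the tuft, and the "pomegranate" texture of nuclei, lumens and
mesangium gives way to a homogeneous matrix. The workflow encodes both cues
as a fixed 150-value descriptor, reduces it with PCA and classifies with a
cross-validated shallow neural-network ensemble.

## Segmentation of white regions (morphology module)

Three parallel colour-space routes each produce a candidate mask of the
white structures:

1. **RGB green plane**, binarised at a fixed threshold of 190 (8-bit
   scale). Green separates PAS-magenta tissue from unstained structures
   best among the RGB planes.
2. **Complement of magenta**, `255·(1−M)` from the naive device CMYK
   conversion (`K = 1 − max(R,G,B)/255`, `M = (1 − G/255 − K)/(1 − K)`,
   `M = 0` where `K = 1`), binarised at the same threshold. Note that this
   plane is bright wherever magenta is absent — including neutral greys —
   so it is meaningful only in combination with the other two routes.
3. **CIELAB chromaticity clustering**: k-means (k = 5, best of 3 restarts
   by within-cluster sum of squares) on the per-pixel (a, b) pairs,
   retaining the cluster with the greatest mean grey-level intensity of the
   original image. CIELAB is computed for sRGB under D65.

Each route is cleaned by median filtering, erosion and dilation with disk
structuring elements (radius 2 by default, configurable 1–3; the
median-erode-dilate order removes speckle without growing blobs) and
refined by a region-based active contour (morphological Chan–Vese, exactly
200 iterations, initialised with the cleaned mask; the route's own channel
image drives the contour, the grey-level image for the CIELAB route).
Empty and full masks are fixed points and skip the contour. Because
Chan–Vese labels its two phases arbitrarily, the brighter phase is kept.

The three masks are fused by per-pixel majority (≥ 2 of 3). Connected
components (8-connectivity) smaller than 1000 pixels are removed, and the
result is intersected with a centred disk of **diameter** 7/8 of the
smaller image dimension. The source text for this last filter reads as a
*radius* of that size, but such a disk would circumscribe the whole image
and filter nothing; the diameter reading is the only one with effect, and
it removes border-touching structures as intended.

Two features summarise the final mask: `white_area_fraction` (mask pixels
÷ image pixels) and `equivalent_radius` = √(area(convex hull)/π) in
pixels, both 0 for an empty mask. The equivalent radius enters the
classifier unnormalised; z-scoring downstream absorbs the scale.

## Texture descriptors (texture module)

**mrcLBP (120 values).** Rotation-invariant uniform LBP (8 circularly
interpolated neighbours, riu2 mapping: 9 uniform codes + 1 non-uniform
bin) applied to each RGB channel at radii 1, 3, 9 and 27 pixels. Eight
neighbours is forced by the 10-bins-per-radius layout (P + 2 = 10). Each
(channel, radius) histogram is normalised to sum 1 over the pixels with a
complete neighbourhood (border pixels excluded); crops must exceed 55
pixels per side for the radius-27 ring. Ordering is channel-major (R, G,
B), radius-minor.

**Haralick (28 values).** The grey-level co-occurrence matrix is computed
at distance 1 for the four standard directions (0°, 45°, 90°, 135°;
offsets (0,d), (−d,d), (−d,0), (−d,−d)), symmetric and normalised to sum
1, on the Rec. 601 luminance quantised to 64 equal-width levels (distance,
level count and the luminance choice are configurable; they are common
defaults, not prescribed values). The 14 classic indices are computed per
direction — angular second moment, contrast, correlation, variance,
inverse difference moment, sum average, sum variance (centred on the sum
average), sum entropy, entropy, difference variance, difference entropy,
the two information measures of correlation, and the maximal correlation
coefficient — then reduced to the mean and the range (max − min) across
directions. Logarithms use the 0·log 0 = 0 convention; correlation-type
indices of degenerate single-level matrices are defined as 0; the maximal
correlation coefficient (√ of the second-largest eigenvalue of the Q
matrix, restricted to levels with non-zero marginals) falls back to 0 when
not finite. These guards keep every descriptor finite on flat patches.

## Feature reduction (preprocess module)

Features are z-scored with the population (1/N) variance convention;
zero-spread features are flagged and mapped to 0. PCA (full SVD) retains
the smallest leading component set whose cumulative explained variance
reaches 99.9% — a deliberately permissive threshold: the classifier, not
the reduction, does the discarding. The reduction uses no labels, so it
may legitimately be fitted on the training portion only (`fit_scope =
"train_only"`, the default, leak-free) or on the whole dataset
(`"whole_dataset"`, which trades a nominal leak for a stabler basis); both
are exposed because they yield nearly identical dimensionality and the
choice is a matter of policy.

## Classifier (classifier module)

One shallow network per cross-validation fold (k = 10): a single
hyperbolic-tangent-sigmoid hidden layer (27 units by default; the size can
be selected by sweeping candidates and maximising the mean fold validation
MCC, ties toward the smaller size), a 2-unit softmax output, mean
cross-entropy loss, trained by Møller's scaled conjugate gradient (a
Hessian-free full-batch method with no line search; one epoch = one SCG
iteration). A stratified 15% of each fold's training part is held out;
training stops when the validation loss has not improved for 6 consecutive
epochs (or at 1000 epochs) and the best-validation-epoch weights are
restored. Five random initialisations compete per fold and the best by
validation MCC is kept. MCC is used throughout model selection because the
classes are ~1:5.5 imbalanced and accuracy saturates.

Each fold receives its own decision threshold from the ROC curve of its
validation scores (counting-based, one point per distinct score):

* **Approach A**: the first curve point touched by a line of slope
  n_negative/n_positive sliding down from (FPR, TPR) = (0, 1) —
  equivalently the maximiser of TPR − slope·FPR.
* **Approach B** (default): the point minimising
  √((1 − sensitivity)² + (1 − specificity)²). B favours recall on the
  disease class and is the shipped default.

The curve-point threshold is a score value; the fold applies the midpoint
between it and the next distinct validation score below it. This realises
exactly the selected operating point on the validation fold while
maximising the score margin — necessary because confident softmax scores
saturate at 1.0, where a cut *at* the score value disenfranchises test
samples at 1 − ε.

Prediction is a hard majority vote of the k fold networks (each votes
positive when its positive-class score reaches its threshold); 5–5 ties go
to sclerotic, since a missed sclerotic glomerulus is the costlier error in
this screening context. All randomness (fold shuffling, inner splits,
initialisations) derives from one seed through spawned seed sequences, so
fits are bit-reproducible and fold order does not affect predictions.

## Evaluation (metrics module)

TP/FP/FN/TN with sclerotic positive; accuracy, precision, recall and MCC
by their standard confusion-matrix formulas. A metric whose denominator is
zero is reported as 0 and flagged (matching the "random predictor ≡ 0"
reading of MCC). Reported tables round to 4 decimals, half-even.

## Synthetic data (synthesis module)

The real dataset behind this workflow (whole-slide images of human kidney
biopsies) is private, so the package ships a generator that emulates the
structure the features target, at desk scale:

* non-sclerotic crops: an elliptic capsule with a thin membrane, a
  near-white annular Bowman's space, 6–12 white lumens, 25–45 dark-blue
  nuclei, pink-magenta matrix with low-frequency mottling;
* sclerotic crops: matrix fills the capsule, no annulus, ≤ 1 lumen
  remnant, 3–9 nuclei;
* per-biopsy stain profiles (saturation scale 1 ± 0.2, small per-channel
  colour shifts) emulating batch-to-batch stain variability;
* optional artefacts (edge-truncated glomeruli, dark stain blobs), flagged
  in provenance, off by default;
* class imbalance 1:5.5 by largest-remainder allocation, so the realised
  ratio is exact up to rounding.

Default conditions: 10 biopsies × 30 glomeruli, 112-px crops with tuft
radii 30–38 px. The crop size is the smallest at which the Bowman's-space
annulus (≈1400–1900 px) comfortably survives the fixed 1000-pixel region
filter while the radius-27 LBP remains defined; it keeps a full pipeline
run to a few minutes on one core. All colours are placed to straddle the
fixed 190 whiteness threshold under every stain profile (white structures
≥ ~235 at baseline, tissue ≤ ~185 in the green plane worst-case).

**What passing on synthetic data does and does not show.** The generator
reproduces the *geometry* and *palette* contrasts the features encode, so
end-to-end success demonstrates that segmentation, descriptors, reduction
and the ensemble compose correctly and that the white-area signal is
recovered. It does not demonstrate performance on real histology: true
PAS crops have far richer texture, touching structures, partial sections
and staining artefacts, and the synthetic classes are more separable than
real ones. Published-scale figures on the private dataset are therefore
not reproduced here, only the workflow that produced them.

## Numerical and degenerate-input policy

* Empty/full masks skip the active contour; empty final masks yield (0, 0)
  morphological features.
* k-means reduces k to the number of distinct chromaticity values when the
  image has fewer, with a warning.
* LBP/GLCM reject images smaller than the neighbourhood/offset, naming the
  offending radius.
* Haralick rejects unnormalised matrices (|sum − 1| > 1e-6).
* PCA keeps at least one component; threshold 1.0 keeps the full rank.
* ROC construction requires both classes; constant scores produce only the
  two degenerate endpoints; threshold ties resolve toward the
  higher-sensitivity point.
* Biopsy-level splitting requires ≥ 2 biopsies and never empties either
  side; the randomized greedy search (200 seeded candidate orders) is
  deterministic per seed.

## Known limitations

* The segmentation stage is tuned to PAS staining; other stains would need
  new thresholds and colours.
* Fold networks are retrained from the feature table when the staged CLI
  pipeline predicts (the bundle persists the split and report, not the
  weights); at this problem size retraining is cheaper than weight
  serialisation, but it couples `predict` to the training configuration.
* The maximal correlation coefficient is numerically fragile by
  construction; the 0 fallback trades fidelity at degenerate matrices for
  finite vectors.
* The generator makes no attempt at photorealism and its sclerotic/
  non-sclerotic contrast is stronger than in real tissue (see above).
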