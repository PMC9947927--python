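# Methods note

This note records what `subloc2l` computes, the parameter choices that pin
its descriptor dimensionalities, the scope of the synthetic generator, the
numerical decisions, and the limitations of the desk-scale evaluation.

## Stain model

An RGB pixel `I` over background intensity `I0` (default 255) has per-channel
optical density `OD_c = max(0, -log((I_c + 1) / (I0 + 1)))`; the +1 offsets
keep the logarithm finite at zero intensity. Given two unit-norm stain color
vectors forming the 3×2 matrix `A` (defaults: hematoxylin `(0.650, 0.704,
0.286)` for DNA, DAB `(0.269, 0.568, 0.778)` for protein), the per-pixel
concentrations solve the least-squares system `A c ≈ OD` via the normal
equations; negative solutions are clipped to zero. Rendering inverts the same
model, so separation of a rendered image is a genuine round trip.

## Descriptor sets and their pinned decompositions

All descriptors operate on the protein concentration map after min–max
rescaling to 8-bit range (constant images map to zeros); neighborhood codes
use interior pixels only, bit 0 at the east neighbor, counter-clockwise bit
order, and the comparison `neighbor >= center`. Every constituent histogram
is L1-normalized. The exact dimensionalities are configuration choices of
this package:

- **SLFs, 840 = 4 + 836.** Four DNA-distribution statistics (protein/DNA
  overlap fraction under Otsu masks; fraction of protein signal inside the
  DNA region; center-of-mass distance over the image diagonal; total
  protein/DNA signal ratio — all finite by construction, degenerate cases
  return 0), plus Haralick features: 11 GLCM statistics × 4 directions ×
  19 distances (1..19) at 64 gray levels, symmetric and normalized.
- **LBP, 256.** The raw 8-neighbor code histogram at radius 1.
- **CLBP, 906 = 3 × 302.** For radii {1, 2, 3} at P = 8 (integer offsets):
  joint sign/magnitude/center histogram on riu2-mapped codes (10 × 10 × 2 =
  200), joint sign/magnitude (100), and the center histogram (2). The
  magnitude threshold is the image-wide mean absolute neighbor difference;
  the center bit compares to the image mean.
- **RICLBP, 408 = 3 × 136.** Four-bit LBP codes paired at displacement along
  four directions; pairs are equivalent under simultaneous 180° rotation of
  both codes and swap, giving (256 + 16)/2 = 136 classes; codes along the
  vertical directions are de-rotated by 90°, which makes the histogram
  exactly invariant to 90° image rotations. Scales (radius, displacement) =
  (1, 2), (2, 4), (4, 8).
- **LET, 413 = 343 + 64 + 6.** A LETRIST-style histogram: joint 7³ codes of
  quantized cross-scale Gaussian gradient magnitudes (σ ∈ {1, 2, 4}), joint
  4³ codes of second-derivative signs, and per-scale 2-bin binary magnitude
  histograms; borders of 8 px are excluded.

## Feature selection

Stepwise discriminant analysis on z-scored columns. Wilks' lambda is
`Λ(s) = det(W_s) / det(T_s)` with within-class and total scatter matrices;
the inclusion statistic for candidate `q` is the partial F,
`F = (N − C − |s|) / (C − 1) · (Λ(s)/Λ(s ∪ q) − 1)`. Defaults `F_enter =
3.84`, `F_remove = 2.71`; ties break toward the lowest column index; if no
feature passes, the single best feature is returned with a warning. Candidate
evaluation is vectorized through Schur-complement determinant updates; a
small ridge is added when scatter matrices are numerically singular.

## Classifier and ensemble

SAE-SM: sigmoid encoders of sizes `h1`, `h2` pretrained greedily as sparse
autoencoders (loss = mean ½‖x̂ − x‖² + β·Σ KL(ρ‖ρ̂) + (λ/2)‖W‖², decoders
discarded), then the full network with a softmax head is fine-tuned with
cross-entropy + L2. Optimization is full-batch Adam (default rate 0.05)
rather than plain gradient descent: plain full-batch GD required thousands
of epochs to fit even linearly separable toys, whereas Adam reaches the same
optima within the default epoch budgets (pretrain 60, fine-tune 150 for
desk-scale data). Glorot initialization from a seeded generator makes
training bit-reproducible; inputs are min–max scaled with the scaler stored
in the model.

The two-level model trains one SDA + SAE-SM per feature set, fuses the per-set
probability outputs by their element-wise mean `F_ME = (1/T) Σ_t p_t`, and
trains a second SAE-SM (hidden sizes 7/7) on `F_ME`. Second-level training
inputs are built by out-of-fold stacking over stratified folds (default 5),
with SDA re-run inside each stacking fold; deployment first-level models are
refit on all training rows afterwards. All child seeds derive from one root
seed via `numpy` seed sequences.

## Evaluation

Overall accuracy, macro precision/recall/F1, the multiclass Matthews
correlation (Gorodkin's R_K over the confusion matrix), and per-class
one-vs-rest ROC AUC and PR AUPR with mean and population standard deviation
over classes (classes absent from the truth are excluded with a warning).
The CV harness is stringent: selection, scaling, stacking and all SAE
training are re-run from scratch inside every fold, and an optional audit
trail records the absolute row indices of every internal fit so leakage is
checkable mechanically.

## Synthetic generator scope

The generator renders seven texture archetypes (nuclear, diffuse
cytoplasmic, small/large vesicles, perinuclear rings, fine/coarse reticular
stripes) over random nuclei discs, through the inverse stain model with
additive Gaussian noise (sd 0.05) in concentration space, and retains the
ground-truth concentration maps. The archetypes are chosen for controllable
spatial-scale contrast and make no biological claim beyond matching the
class count of a typical localization label set. Desk-scale study
conditions: 15 images per class at 128 × 128 px.

## Limitations

- All quantitative results in this repository are computed on synthetic
  desk-scale corpora; no claim is made about accuracy on real IHC image
  collections, which require corpora not packaged here.
- The descriptor decompositions above are pinned package choices; other
  published variants of CLBP/RICLBP/LETRIST differ in binning and mapping
  details while keeping the same total dimensionalities only under specific
  configurations.
- The stain model is linear two-component Beer–Lambert; it does not model
  stain co-localization saturation, scattering, or more than two stains.
- The optimizer deviates from plain full-batch gradient descent (see above);
  with Adam the loss trajectory is not guaranteed monotone, though the
  training-contract tests check non-increase over the configured budgets.
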