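# Methods

This note documents the models and procedures implemented in `btfsc`, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish about behavior on real data.

## Scope and data model

The package implements a per-slice pipeline for paired, co-registered 2-D
modality images: denoising, edge analysis, convolutional fusion, fuzzy
clustering segmentation, hybrid feature extraction and binary
classification. All images are `float64` arrays on the [0, 1] intensity
scale; noise levels are quoted on the 8-bit 0–255 scale (the scale on which
the denoiser's window rule is defined) and converted internally. 3-D
volumes, DICOM/NIfTI ingestion and acquisition physics are out of scope.

## Synthetic phantoms (`btfsc.phantom`)

Each phantom is a skull ellipse (bone band plus nested soft-tissue
plateaus) with an optional planted tumor, rendered into two channels with
different contrast: the MR-like channel makes soft tissue and the tumor
hyperintense; the CT-like channel makes the bone band bright and soft
tissue flat. Acquisition noise is additive zero-mean Gaussian, X = O + G,
clipped to the intensity range — clipping rather than rescaling mirrors
8-bit acquisition and keeps PSNR oracles simple.

Class structure. Benign tumors are smooth ellipses with a flat interior.
Malignant tumors differ in exactly two controlled ways: (1) the boundary
radius is perturbed by low-order Fourier modes (m = 3..6) with total
relative amplitude `boundary_irregularity` (default range 0.25–0.45 in the
dataset generator), and (2) the interior receives band-limited
multiplicative texture (Gaussian-smoothed white noise, unit variance,
clipped at 1.5 sd, relative amplitude 0.12–0.20). These defaults were fixed
once as values that give the texture features a realistic but not trivial
margin; they are the "study conditions" for every training and recovery
result below.

The default phantom has four intensity groups — background, bone band, one
soft-tissue plateau, tumor — matching the segmenter's default k = 4; extra
plateaus can be requested per spec (`tissue_levels`), in which case k must
be raised accordingly.

Determinism: a phantom spec's seed is split into independent child streams
for geometry/texture and for each channel's noise, so the *same* spec with
`noise_sigma = 0` yields exactly the clean images underlying a noisy
render. This is what allows PSNR-against-ground-truth tests at all.

What the phantoms do **not** emulate: anatomical shape variability, partial
-volume effects, bias fields, Rician noise, real BraTS intensity
distributions. Recovery results below therefore demonstrate correctness of
the algorithms under their stated assumptions, not clinical performance.

## Adaptive denoiser (`btfsc.denoise`)

Noise estimation uses the mean absolute response to the 3x3 high-pass
operator [[1,−2,1],[−2,4,−2],[1,−2,1]] scaled by sqrt(pi/2)/6 (the operator
annihilates constant and linear structure, so the mean absolute response
estimates the Gaussian noise floor). The window rule is exact: 3x3 for
sigma < 20 (0–255 scale), 5x5 at or above.

The filter itself is selection-based, applied per window: mean-filter the
image (X~), form D = |X − X~|, compute the local mean mu of D over the
window, keep the observed pixel where D < mu ("uniform" pixels) and the
mean-filtered value where D >= mu (outliers), then output the window mean
of the selected field. Two consequences are tested as invariants: constants
pass through unchanged, and the output never leaves the input's intensity
range (it is an average of observed values and of averages of observed
values). Reflect padding is used for all windowed operations to avoid
dark-frame artifacts. The comparison value mu is the *local* mean of D —
a global mu was considered and rejected because local adaptivity is the
stated point of the filter.

## Robust edge analysis (`btfsc.edges`)

REA decomposes an image into a Canny edge map (after Gaussian
pre-smoothing), a smooth slope field, and a per-pixel energy map. The slope
field R minimizes the two-term quadratic energy

    E(R) = xi * sum((R − M − C')^2) + sum((R − M + C')^2),

with M the mean-centered image and C' the Gaussian-smoothed gradient
magnitude (the only edge-carrying quantity available; this reading of C' is
an interpretation and flagged as such). Minimization is plain fixed-step
gradient descent (step 0.1/xi, relative-change tolerance 1e-4, at most 200
iterations) with the energy trace recorded; the descent property is
asserted in tests. At xi = 1 the initial point R = M is already stationary
and the optimum is R = M exactly; the closed-form optimum is
R = M + C'(xi−1)/(xi+1), so the final energy grows monotonically with xi —
also asserted. Pixels with gradient magnitude below the lower Canny
threshold are flagged smooth and carried by the slope field; the rest are
described by the energy map. The resampling operator in the energy is the
identity at equal shapes (the per-slice setting); no multi-resolution
registration is attempted.

## Fusion network (`btfsc.fusion`)

Topology (fixed): stage 1 convolves each input with a *shared* 3x3 bank
(64 maps, ReLU); the two branch outputs are summed and convolved with a
shared stage-2 bank (128 maps, ReLU); because the two stage-2 expressions
are symmetric in F1 + F2, the two stage-2 maps F3 and F4 are *identical* —
this is implemented as written and asserted, not "fixed". Stage 3 projects
the concatenation [F3, F4] to one channel (ReLU, clipped to [0, 1]).
Same-padding keeps full resolution, which segmentation requires; the
declared map counts (64/128) are kept. Internally the stage-3 convolution
is computed as conv(F3, W3a + W3b), exactly equal to the concatenated form
since F4 aliases F3.

Training (the recipe is this package's own, since only the topology is
prescribed): unsupervised loss

    L = 0.4*(1 − SSIM(F, a)) + 0.4*(1 − SSIM(F, b)) + 0.2*L_grad,

where L_grad matches the fused forward-difference gradients, per pixel and
direction, to whichever source gradient is larger in magnitude. The SSIM in
the loss uses a flat 7x7 window with circular boundary handling, which
makes its analytic gradient exact (verified against finite differences);
*evaluation* SSIM everywhere else is the canonical Gaussian-window form
(11 px, sigma 1.5, K1=0.01, K2=0.03) from scikit-image. The optimizer is
Adam (lr 1e-3), seeded; there is no autodiff in the stack, all backward
passes are written out and gradient-checked.

Initialization is average-preserving: small He-scaled noise plus a
deterministic delta-kernel path through map 0 of every stage, so the
untrained network computes approximately the pixel average of its inputs.
A short training run then refines a sensible fusion instead of first having
to rediscover one from noise, and the pixel-average baseline used in the
acceptance checks is meaningful at every epoch.

REA integration: the written equations admit two single-channel branches
with one shared stage-1 bank, so the edge-slope product cannot enter as an
extra channel; instead the second branch input is additively enhanced with
the normalized REA energy map (gain 0.2), flag default on. The SSIM loss
always targets the *original* images; enhancement only alters the network
input.

Color modalities (PET/SPECT-like RGB) are fused on the luma channel:
BT.601 YCbCr with offset-0.5 chroma, fuse Y against the grayscale modality,
re-attach Cb/Cr, invert.

## Segmentation (`btfsc.segmentation`)

Per-pixel features (intensity, 3x3 local mean) are projected to a scalar
u = sum_i w_i x_i with weights (1.0, 0.5) — the weights are exposed;
the local-mean feature adds mild spatial regularization. Initial centroids
are deterministic: sort u, split into k contiguous equal-size blocks
(remainder spread to leading blocks), take block means. Fuzzy c-means with
fuzzifier m = 2, Euclidean distance, tolerance 1e-4 on the centroid shift
and at most 100 iterations then refines; a point coinciding with a centroid
receives hard membership there. The objective sum u_ik^m d_ik^2 is recorded
every iteration and is non-increasing (alternating-minimization descent).
k defaults to 4 (background, bone boundary, tissue, tumor — the default
phantom's visual structure); the tumor cluster defaults to the one with the
highest mean source intensity, is recorded in the result, and can be
overridden. Constant or k-level images are rejected as degenerate. The
algorithm family is sometimes described with a kernel variant; plain
Euclidean distance is implemented, as the defining iteration prescribes.

## Hybrid features (`btfsc.features`)

GLCM: 8 quantization levels over [0, 1], offset (0, 1), symmetric,
normalized (defaults chosen to keep toy oracles hand-checkable; pair
counting is delegated to `skimage.feature.graycomatrix`). The five
statistics — contrast, homogeneity, correlation, ASM, energy = sqrt(ASM) —
are authored here and verified against a double-loop oracle at 1e-10.
Correlation of a constant region is undefined (zero marginal variance) and
reports the documented fallback 1.

RDWT: a two-level undecimated (a trous) Haar transform with *unit DC gain*
and *circular* boundary, computed directly (four rolled adds per level).
Unit gain makes the constant-image oracle exact (energy of constant c is
c^2); circular boundaries make every LL-band statistic exactly invariant
under circular shifts — including the GLCM-correlation of the band, which
is computed with wrap-around pair offsets for the same reason. Entropy is
Shannon entropy of the 256-bin LL histogram in bits. Only LL bands carry
features; detail bands are out of scope.

Color statistics are the mean and population standard deviation, with the
square-grid normalization generalized to M x N.

The 13-entry order is [5 GLCM, 6 RDWT, 2 color]. Features are computed on
the bounding-box crop of the segmented region; a whole-image mode exists.

## Classifier (`btfsc.classifier`)

Geometry (self-checking at construction): 64x64 input, conv 3x3/32 valid
(62), max-pool 2x2 (31), conv 3x3/64 (29), max-pool 2x2 (14), flatten
12544, dense 128 ReLU, 2-way softmax head. The input size 64 is the only
one consistent with the printed chain. Training is plain seeded SGD,
batch 90, lr 0.02, cross-entropy; the default 300 epochs is the published
recipe, and scaled-down epoch counts (30) are used for desk-scale runs.
With `feature_concat` the 13-entry hybrid vector, z-scored with training
-set statistics, is concatenated to the dense output before the head. The
"probabilistic" aspect of the model is the softmax posterior; no Parzen
window machinery is present. The numpy layer stack (`btfsc._nn`) provides
im2col convolution with explicit, gradient-checked backward passes.

## Metrics (`btfsc.metrics`)

Entropy: 256-bin histogram, bits. MI: 256x256 joint histogram, log base 2,
*summed* over the two sources (the common convention in fusion work; an
averaged variant would halve the number). With equal binning MI(x, x) =
H(x) exactly, which is asserted. Note that the plug-in MI of *independent*
images is not 0 but the classic finite-sample bias
(K−1)^2/(2N ln 2) ≈ 0.72 bits at 256 bins and 256^2 pixels; tests assert
that floor rather than zero. PSNR is capped at 100 dB for identical
images. SSIM uses the canonical constants above. The confusion panel
computes the ten closed-form binary metrics with division-by-zero cells
reported as 0 and flagged in `degenerate`; the complementarity identities
(FPR = 1 − specificity, FNR = 1 − sensitivity, FDR = 1 − precision) hold
exactly on nondegenerate inputs. 8-bit entropy is bounded by 8 bits by
construction.

## Pipeline (`btfsc.pipeline`)

Stage order is fixed (denoise, rea, fuse, segment, features, classify);
stages can be disabled from the tail, each enabled stage validates its
upstream dependency, and disabling a stage never changes upstream outputs.
One master seed exists in the config; per-stage seeds are derived by stable
hashing of stage names (all shipped stages are deterministic, so this
matters only for user extensions). Viewable artifacts are 8-bit PNG; float
tensors travel as `.npz` archives with a JSON manifest entry.

## Problem sizes used in the shipped checks

Acceptance-style runs use 128x128 phantoms; 20 phantoms per noise level for
denoising gains; 5 seeds x 4 noise levels at 256x256 for estimator
calibration; 8 pairs x 30 epochs for fusion training; 400 training / 100
held-out ROIs x 30 epochs x 3 seeds for classifier recovery. These sizes
were chosen so a complete run finishes in minutes on one CPU core while
leaving each check's margin far from its threshold.

## Known limitations

* Segmenting the *fused* MR+CT image can merge the bone band with the
  tumor: bone is bright in CT, tumor in MR, and their fused intensities can
  coincide, which costs precision (sensitivity stays high). This is an
  intrinsic property of intensity clustering on average-like fusions —
  clinical pipelines skull-strip first, which is out of scope here. The
  clustering stage itself is validated on single-modality denoised input.
* The fusion loss's uniform-window SSIM is a training surrogate; reported
  SSIM always comes from the canonical Gaussian-window implementation.
* The noise estimator is biased upward on structure-rich images (its
  calibration statement holds on pure noise fields) — downstream use only
  needs the 3/5 window decision, which is robust to that bias.
* Plug-in MI carries the finite-sample bias discussed above; values near
  0.7 bits for 256x256 images indicate independence, not weak coupling.
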