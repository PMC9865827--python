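# btfsc — multimodal brain-tumor image pipeline on synthetic phantoms

`btfsc` is a research implementation of a classic hybrid pipeline for
brain-tumor analysis on paired, co-registered 2-D modality slices
(MR-like soft-tissue contrast + CT-like bone/edge contrast):

1. **Denoise** each channel with an adaptive selection filter (HPWF): the
   noise level σ_GN is estimated from the mean absolute response to a 3×3
   high-pass operator, the working window is 3×3 when σ_GN < 20 (0–255
   scale) and 5×5 otherwise, and each pixel is replaced by the window mean
   of a selected field that keeps "uniform" pixels (|X − X̃| < μ) and
   substitutes the mean-filtered value elsewhere.
2. **Edge analysis (REA)**: Canny edges plus a slope field minimizing
   E(R) = ξ‖R − M − C′‖² + ‖R − M + C′‖² by recorded gradient descent.
3. **Fuse** the pair with a two-branch convolutional network
   F₁ = ReLU(W₁∗a + B₁), F₂ = ReLU(W₁∗b + B₁),
   F₃ = F₄ = ReLU(W₂∗(F₁+F₂) + B₂), F_R = ReLU(W₃∗[F₃,F₄] + B₃),
   trained unsupervised toward SSIM with both sources plus gradient
   preservation.
4. **Segment** the result with weighted-ranking k-means initialization
   (sorted u_j = Σᵢ WᵢXᵢ split into k blocks) refined by fuzzy c-means
   (m = 2, Euclidean distance, non-increasing objective).
5. **Featurize** the tumor region: 5 GLCM statistics (contrast,
   homogeneity, correlation, ASM, energy = √ASM), 6 undecimated-Haar
   LL-band statistics (entropy, energy, GLCM-correlation at two levels)
   and 2 color moments — a fixed 13-entry vector.
6. **Classify** benign vs malignant with a small CNN
   (64→62→31→29→14, flatten 12544, dense 128, 2-way softmax), optionally
   concatenating the z-scored hybrid features before the head.

Because the public benchmark the design targets is not redistributable,
the package ships a first-class **phantom generator**: co-registered
modality pairs with planted tumors whose mask, class label (boundary
irregularity + interior texture distinguish malignant from benign) and
noise level are known exactly. Every stage is therefore testable against
ground truth, end to end, on a laptop. The intended audience is
researchers who want a transparent, fully seeded reference implementation
of this pipeline family rather than a clinical tool.

## Worked example

```bash
python examples/02_denoise.py
```

```
injected sigma      : 15.0 (0-255 scale)
estimated sigma_GN  : 13.86
window chosen       : 3x3
PSNR noisy vs clean : 25.50 dB
PSNR denoised       : 30.88 dB   (gain +5.37 dB)
```

The estimator reads the injected noise back from the image (13.9 vs 15;
the small downward bias comes from clipping at the intensity bounds),
picks the 3×3 window because σ_GN < 20, and the filter gains +5.4 dB PSNR
against the known clean phantom — denoising, not just blurring.

```bash
python examples/05_segment.py
```

```
centroids (weighted scale): [0.079 0.238 0.524 1.288]
tumor cluster id          : 3
tumor pixels found/truth  : 470/496
Dice vs ground truth      : 0.961
```

The four centroids land on the phantom's four intensity groups
(background, bone band, tissue, tumor); the brightest cluster recovers the
planted tumor mask at Dice 0.96.

The other examples (`examples/01` … `08`) walk through phantom generation,
edge analysis, fusion training, feature extraction, classification
(held-out accuracy 1.000 on a small run) and the full pipeline with all
three metric panels.

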