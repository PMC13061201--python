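# Methods

This note records the models the package implements, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic experiments do and do not demonstrate.

## Preprocessing

Images are resized so the longest dimension matches the network input size
(default 256 px) with bilinear interpolation, min–max normalized to [0, 1],
and zero-padded to a square. Masks follow the same geometry with
nearest-neighbour interpolation so values stay exactly binary. Choices:

- **Padding side.** Bottom/right only. Any convention works; this one makes
  the coordinate mapping `padded = original × scale` exactly invertible with
  zero offsets, which `PadRecord` exposes for mapping predictions back.
- **Constant images** normalize to all zeros with a logged warning rather
  than raising: degenerate frames occur in practice (e.g. frozen frames)
  and should not abort a batch pipeline.
- **Masks are binarized at load** (any nonzero value → 1); multi-class masks
  are out of scope.
- All internal processing is single-channel. Replication to three channels
  belongs at the model-input boundary of whatever network consumes the
  data; augmentation math is channel-agnostic.
- Resizing is implemented with Pillow (float-mode bilinear, nearest for
  masks). Nearest-neighbour resampling trivially preserves the binary label
  set, which the test suite verifies for scale factors in [0.1, 4].

## The SAS augmentation

- **Thumbnail size** is uniform over integers [64, 256] at the 256-px input
  size (scaling ratios 0.25–1). The distribution is a choice — only
  "randomly selected" is inherent to the method — and uniform is the least
  informative option.
- **Placement** of the thumbnail on the zero canvas is uniformly random with
  the thumbnail fully inside (adds translation variety, never crops
  content); a `centered` mode exists for reproducibility tests.
- **Noise magnitudes** (nothing about them is canonical): Gaussian and
  speckle variance 0.01, salt & pepper amount 0.05 with a 50/50 salt/pepper
  split, Poisson photon scale 255 (i.e. intensities are treated as mean
  photon counts out of 255). All are exposed in `SASConfig.noise_params`.
  At these defaults the perturbation is visible but does not destroy the
  structure's echogenicity contrast.
- **Noise is applied after scaling**, on the thumbnail-resolution mask, and
  the ROI is exactly the foreground mask — not a bounding box — so the
  background stays bit-identical (asserted per pixel in tests).
- **Size threshold** 0.03 is inclusive: a mask occupying exactly 3% of the
  image is *small*. Classification always uses the area ratio measured
  before any transform; a thumbnail-scaled large structure remains
  "large" for policy purposes.
- **The 50% policy** applies SAS only to large-structure images. Small
  images are never transformed — shrinking already-small targets would
  push them below usable resolution.

## Click-prompt simulation

- The **initial click** is uniform over the foreground pixels whose
  boundary distance (exact Euclidean distance transform, image border
  counting as background) is at or above the 70th percentile of foreground
  distances — the "deepest 30%" of the structure. The alternative reading
  (bottom 30% of distances) would place first clicks at the rim, which
  contradicts the near-centroid intent, so it was rejected.
- **Refinement clicks** operationalize "the region with the highest error"
  as the largest 8-connected component of the error map, clicked at its
  interior-most pixel (max boundary distance, row-major tie-break). This is
  deterministic given the error map; a random-pixel variant would add
  variance without changing labels.
- An **empty error map is a terminal state** (convergence), not an error:
  `simulate_click_sequence` stops early and the final prediction is carried
  forward for the remaining click budget during evaluation.
- Coordinates are 0-based, x = column, y = row, stated in every serialized
  output. Bounding-box prompts exist only as a tight-box utility.

## Metrics

- DSC and NSD are computed exactly; NSD membership in the tolerance region
  β(τ) uses the exact Euclidean distance transform of the *boundary* sets
  rather than a discrete-ball dilation, removing structuring-element
  ambiguity. Boundaries are foreground pixels with a 4-neighbour background
  pixel, the image border counting as background.
- **τ defaults to 2 px**, the convention of the promptable-medical-
  segmentation evaluation lineage; it is a mandatory, logged column of
  every report because NSD values are meaningless without it.
- **Empty-mask conventions**: both masks empty → 1 (nothing to get wrong);
  exactly one empty → 0 (no boundary can be within tolerance of a missing
  one). These are documented choices.
- Confidence intervals are percentile bootstraps of the mean, 10,000
  resamples, seeded.
- Both metrics are validated against brute-force oracles: exhaustive
  enumeration of all 512 3×3 masks for DSC, all-pairs boundary distances on
  random 16×16 masks for NSD.

## Synthetic phantoms

The generator emulates the *display statistics* of B-mode frames, not the
physics: a smooth low-frequency tissue field multiplied by unit-mean
gamma-distributed speckle (variance configurable, default drawn from
[0.02, 0.08]), masked to a sector, convex (annular-sector) or rectangular
viewport with every outside pixel exactly zero. The target organ is an
ellipse or a "blob" (ellipse modulated by 2–4th-order radial harmonics,
renormalized to preserve area) with a hypoechoic offset (default −0.25 to
−0.4), and the realized mask area is iteratively corrected to within 20%
(in practice 5%) of the requested relative area. **Distractor structures**
— a few non-target regions with similar echogenicity — are rendered into
the image but not the mask, because real frames never contain a single
isolated hypoechoic region; without them, echogenicity alone would identify
the target and scale augmentation would have nothing to contribute.

The default size mixture is 70% small (log-uniform relative area in
[0.004, 0.025]) and 30% large (uniform in [0.04, 0.25]). The ranges stop
short of the 0.03 class boundary so rasterization tolerance cannot flip a
sample's intended size class. Large organs get proportionally smoother
outlines, and a draw that cannot fit inside a fan viewport falls back to a
rectangular (linear-probe-like) frame.

What the phantoms do **not** model: attenuation, shadowing/enhancement,
probe-specific point-spread anisotropy, anatomy-specific appearance, or
multi-structure masks. Consequently, passing synthetic tests shows the
augmentation/prompting/metric machinery behaves correctly and that the SAS
effect direction emerges under a controlled scale shift — it does not
predict absolute performance on clinical data.

## Reference model and training harness

No deep-learning framework is used: the reference model (`ClickNet`) is a
one-hidden-layer (16-unit, tanh) per-pixel classifier over seven feature
maps — raw and smoothed intensity, gradient magnitude, local texture
energy, intensity contrast against the tissue at the positive clicks, and
normalized distances to the nearest positive and negative click — with
hand-written gradients verified against finite differences. It is a
deliberately small stand-in for a promptable segmentation network that
still reproduces the failure mode of interest: the click-distance channels
are in absolute (normalized) pixels, so a model fitted only on large
structures learns a large effective radius and over-segments small targets.

- **Loss**: pixelwise binary cross-entropy plus soft-Dice loss with
  additive smoothing ε = 1, summed unweighted.
- **Optimizer**: hand-rolled AdamW, β₁ = 0.9, β₂ = 0.999, decoupled weight
  decay 0.01, batch size 8. The `TrainConfig` default learning rate is
  5 × 10⁻⁵, appropriate for fine-tuning a pretrained multi-million-
  parameter network; the desk-scale ablation overrides it to 3 × 10⁻²
  because a ~200-parameter model trained from scratch needs far larger
  steps to converge within its epoch budget (convergence was checked on
  training curves, not on test outcomes).
- **Early stopping** monitors validation compound loss with patience 5;
  the returned checkpoint is the epoch with the best validation metric,
  taken to be mean DSC at one click (the natural single-number summary of
  a click-promptable model).
- **Training-time clicks** are re-simulated against the current model every
  epoch (1–3 clicks per sample, drawn per presentation), so the model
  learns to use refinement clicks, not just the initial one.

## The ablation experiment

`run_sas_comparison` generates a training pool dominated by large
structures (80% large) and a test set dominated by small ones (80% small)
— the distribution shift the augmentation targets — and trains the four
arms (no SAS, noise only, scale only, SAS) from identical initialization on
byte-identical raw samples; only the augmentation stream differs. Problem
sizes are desk-scale choices: 200 training / 40 validation / 50 test
phantoms at a 128-px input size (thumbnails 32–128 px preserve the 0.25–1
ratio range), up to 15 epochs, evaluated at 1–8 clicks with 10,000-resample
bootstrap CIs (1,000 in the repeated-seed tests). The tested claims are
directional and ordinal — SAS beats no-SAS on small structures at one
click, and matches or beats each single-perturbation arm at eight clicks,
in the median over three seeds — never absolute scores, which depend on
the phantom difficulty and the tiny model's capacity.

## Known limitations

- The phantom generator's realism gap (above) bounds what synthetic
  experiments can claim.
- The reference model has no receptive field to speak of; boundary accuracy
  (NSD) saturates well below what a convolutional network achieves.
- DICOM support reads pixel data only; the ultrasound window rectangle must
  be supplied explicitly (vendor region-calibration tags vary too much to
  parse generically).
- Single-structure binary masks only; no video, no 3-D.
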