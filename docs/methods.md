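# Methods

## Problem and model

Anisotropic 3D reconstructions of coronal brain-slab photographs have
in-plane resolution near 1 mm but through-plane (anterior–posterior, AP)
spacing of 4–12 mm — the slab thickness.  `slabimpute` recovers a 1 mm
isotropic volume by *slice imputation*: for every target coordinate
between two observed slices x₁ (anterior) and x₂ (posterior) at
distances d₁ and d₂, it predicts

    ŷ(x₁, x₂, d₁, d₂) = y_lin + S_θ(x₁, x₂, d₁, d₂),
    y_lin = (d₂/d)·x₁ + (d₁/d)·x₂,          d = d₁ + d₂,

where y_lin is the distance-weighted linear interpolation and S_θ is a
2D U-Net predicting only the residual.  Residual learning starts from a
sensible baseline (the zero-initialized output head makes the untrained
network an exact linear interpolator) and converges much faster than
predicting intensities directly.  Working slice-by-slice keeps memory
small, makes inference independent per coordinate (so variable
inter-slice spacing is handled naturally), and avoids the volumetric
hallucination that global 3D losses can introduce.

The network input has four channels: x₁, x₂, and the two distances
replicated into constant planes (in mm, unnormalized — the range
[0, 12] mm is small enough not to need rescaling).  RGB stacks are
processed per channel with identical queries.

## Network

Four encoder and four decoder resolution levels with symmetric blocks.
Each unit is Group Normalization → 3×3 convolution ("same" zero
padding) → Leaky ReLU (slope 0.01); encoder blocks contain two units
followed by 2×2 max-pooling, halving resolution and doubling channels
per stage.  With the default base width 64 the encoder schedule is
64/128/256/512 and the bottleneck reaches 1024 channels.  The decoder
mirrors the encoder with bilinear 2× upsampling and concatenated skip
connections; a zero-initialized 1×1 convolution with no activation
produces the (possibly negative) residual.

One deliberate deviation inside the first block: the **first** encoder
unit applies its convolution directly to the raw input, without
normalization.  Group-normalizing the 4-channel input would standardize
each group to zero mean and unit variance, and a constant plane has
zero variance — the distance-conditioning channels d₁, d₂ would be
annihilated before reaching any convolution, leaving the predictor
blind to the coordinate it is asked to impute.  All subsequent units
normalize as usual (8 groups, capped at the channel count and reduced
to a divisor where needed).

The network is implemented directly on NumPy arrays with hand-written
backward passes for every layer (im2col convolutions on a channels-first
layout so each conv is a single BLAS matmul; exact adjoints for pooling
and bilinear upsampling).  All gradients are verified against central
finite differences in the test suite.  `float64` is the default for
analytic tests; the training profiles use `float32`.

Spatial sizes must be divisible by 16 (four poolings); other inputs are
symmetric-padded and cropped back at inference.

## Synthetic training data

Training never sees real photographs.  Each iteration synthesizes one
pseudo-photograph volume from a randomly chosen 3D label map:

1. **Geometric augmentation.** A random affine (rotation ±15°, per-axis
   scale [0.85, 1.15], shear ±0.1, translation ±10 mm) composed with a
   smooth random displacement field (component sd 4 mm).  The field's
   correlation length is 5 mm along AP versus 20 mm in-plane: it varies
   *faster* through-plane, emulating the imperfect AP alignment of real
   photograph stacks.  Labels are resampled with nearest-neighbor
   interpolation (they are categorical).
2. **GMM synthesis.** Each voxel's intensity is drawn from a Gaussian
   conditioned on its label; per-label means ~ U[0, 255] and sds
   ~ U[0, 25] are re-randomized per volume, so the network is agnostic
   to appearance.
3. **Gamma augmentation.** Min-max normalization to [0, 1] followed by
   a random power γ = exp(U[−0.3, 0.3]), skewing the histogram.
4. **Illumination.** Multiplication by exp(smooth field, sd 0.2) with
   correlation 8 mm (AP) / 32 mm (in-plane) — uneven lighting changes
   more between slabs than within one.

Smooth fields are white noise on a coarse grid (spacing = correlation
length) upsampled linearly and rescaled to the target pointwise sd; the
AP-faster-variation property is asserted empirically via autocorrelation
half-widths.  None of these ranges is canonical — the published
description leaves them numeric-free — so they follow the conventions
of SynthSeg-family generators and are all exposed in `SynthConfig`.

**Digital slabbing** then cuts 32 triplets per volume: thickness d ~
U[2, 12] mm, anterior face a uniform such that the slab fits, target at
a + d₁ with d₁ ~ U(0, d).  Slices at continuous AP coordinates are
extracted by linear interpolation of the 1 mm grid; x₁/x₂ are single
extracted planes (not thickness-averaged slab faces).

## Loss and optimization

The loss is MAE between min-max-normalized predicted and target slices
plus λ (default 1.0) times the MAE between their Sobel gradient
magnitudes (3×3 kernels, reflected borders).  Triplets are normalized
jointly by the min/max of their bounding pair before both the forward
pass and the loss, so the baseline remains a convex combination on the
unit scale; the Sobel term's gradient uses the exact adjoint of the
reflect-padded correlation with a zero subgradient where the magnitude
vanishes.

The full-fidelity profile is Adam at learning rate 10⁻⁶ on batches of
32 triplets, early-stopped on the MAE over a frozen validation set of
1,000 synthetic slices (no improvement > 10⁻⁵ for 10 consecutive
checks); the parameters with the best validation MAE are kept.

A **scaled profile** (`TrainConfig.scaled()`) makes the whole study
reproducible on one CPU core in minutes: base width 8 (128-channel
bottleneck), 64×64 slabs from three folded phantoms, batches of 16,
learning rate 3×10⁻⁴, 300 iterations, a frozen 100-slice validation
set.  The higher learning rate is a convergence-speed choice for the
small network; batch and iteration counts were sized so the whole
5-seed suite plus end-to-end evaluation runs in minutes.  At this scale
the trained network undercuts the frozen S_θ ≡ 0 linear baseline by
roughly 1% validation MAE — small in absolute terms because the
synthetic slices carry irreducible per-voxel GMM noise that no
predictor can reconstruct; the learnable margin lives at structure
boundaries.

## Inference

Targets are placed on an arithmetic grid (default 1 mm) aligned at the
first observed slice and spanning exactly the observed range — the
model never extrapolates beyond the first/last slab face, where only
one informative slice would be available.  Targets within 10⁻⁶ mm of an
observed coordinate copy the observed slice verbatim (bit-exact
passthrough).  Slab thicknesses outside the trained [2, 12] mm range
produce a warning, not a refusal: the network is conditioned on
distances and may extrapolate.

The network sees the bounding pair normalized by its joint min/max; the
predicted residual is scaled back by that range and added to the
raw-scale linear baseline, keeping intensity continuity across slabs.
Residual-corrected pixels that leave the pair's intensity range are
clipped back; the baseline itself is never altered, which keeps the
zero-residual network an exact linear interpolator (and linear ramps
exactly reconstructible).

## Evaluation metrics

* **Dice** 2|A∩B|/(|A|+|B|) per label, requiring a shared grid
  (an opt-in nearest-neighbor resampler is provided; resampling changes
  scores, so it is never implicit).  Conventions: empty-empty = 1.0
  (flagged), present-in-one = 0.0.
* **Closest-point surface distance**: per-vertex point-to-*triangle*
  distance (vectorized region-case analysis, chunked over vertices),
  asymmetric src→ref; per-parcel means are averaged unweighted
  (mean of parcel means, so small parcels count equally).
* **Cortical thickness**: one-directional white→pial closest-point
  distance; thickness error is the per-parcel absolute difference of
  mean thicknesses, plus the grand mean.  This is a closest-point
  proxy, not the full FreeSurfer-style definition.

## Phantoms

Real training would use thousands of FreeSurfer segmentations; the
package substitutes procedural phantoms — nested ellipsoidal shells
(background / folded outer "cortex" ribbon / "white matter" core /
optional "ventricle" cavity) whose outer boundary is perturbed by
seeded sinusoidal folds.  Coarse AP sampling visibly degrades the
folded ribbon, reproducing the failure mode that motivates imputation.
The phantoms exercise every code path but are *not* anatomy: passing
tests demonstrate correctness of the machinery and the relative
benefit of residual learning over linear interpolation under the
generator's assumptions (Gaussian intensities, smooth multiplicative
illumination), not clinical performance.  Deferred likewise are light
reflection, blood traces, uneven physical slab thickness and other
non-Gaussian effects of real photographs.

## Numerical choices and limitations

* Determinism: every sampler takes an explicit `numpy.random.Generator`;
  with fixed seeds, replay is bit-identical on the same
  hardware/threading configuration.
* Degenerate rules (all logged): constant slices min-max-normalize to
  zeros; a constant volume under gamma augmentation returns zeros; an
  empty parcel is excluded from parcel means.
* Checkpoints are single-file `.npz` archives holding parameters,
  architecture metadata and a config hash; save/load round trips are
  bit-exact.
* Problem sizes in the shipped tests and the acceptance script (64×64
  in-plane, 64×64×80 phantom volumes, 300-iteration scaled training,
  100-slice validation) are the package's scaled-down study conditions;
  the full-scale profile is provided but takes GPU-scale resources.
* The upstream photograph-to-volume registration, segmentation and
  surface-extraction tools are out of scope; the metrics evaluate
  whatever segmentation/mesh pairs they are given.
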