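# Methods

## Problem setting

Intra-patient multi-modal registration of head volumes: a fixed MRI-like
image and a moving CT-like image of the same anatomy differ by a rigid-body
transform (rotation + translation), adequate for same-patient head imaging.
Intensity scales of the two modalities are unrelated (bone is bright in CT,
dark in MRI), which rules out direct intensity matching and motivates
mutual-information objectives and learned features.

## Coordinate and transform conventions

* Voxel indices are 0-based; the world coordinate of voxel `(i, j, k)` is
  `origin + (i, j, k) ⊙ spacing` (voxel-center convention, mm).
* A rigid transform maps moving-image world coordinates onto fixed-image
  world coordinates.  Volumes are resampled by inverse warping
  (`out(x) = in(T⁻¹x)`) with trilinear interpolation and fill value 0;
  coordinates a rounding error outside the grid are snapped to the border.
* The 6-parameter encoding uses intrinsic Z–Y–X Euler angles in degrees,
  rotation about the volume's physical center, and translations in voxels
  of the reference grid (converted to mm via its spacing).  At gimbal lock
  (|ry| = 90°) the decomposition fixes rz = 0; the returned parameters
  always regenerate the same matrix.  Both choices are documented
  conventions rather than consequences of the method: any fixed convention
  works, but it must be fixed for round-trips to be testable.

## Synthetic phantoms: what they emulate, what they do not

The phantom is an ellipsoidal head (semi-axes a > b > c, default
22 × 16 × 5.2 mm on a 64 × 64 × 16 grid at 1 mm spacing) with a bony shell
(outer 15% of the radius), two off-center internal ellipsoids ("CSF" and a
lesion-like structure), rendered under two injective tissue→intensity maps
and additive Gaussian noise (sd 0.02 on a unit intensity scale).  Geometry
is evaluated analytically in world coordinates, so a phantom can be posed
exactly without resampling error.  Default sizes keep a full pipeline run
at desk scale on one CPU.

Design notes:

* The off-center structures break rotational symmetry about the long axis;
  a plain ellipsoid would leave one rotation unidentifiable for parameter
  regression.
* The two modality maps invert the bone/CSF ordering so the voxelwise
  intensity relation between modalities is non-monotone — genuinely
  multi-modal in the sense that matters for MI and feature learning.
* Not emulated: MR bias fields and k-space artefacts, CT beam hardening,
  Rician/Poisson noise, anatomical variability beyond jittered semi-axes,
  structure poses, and a small per-subject pose jitter (±2°, ±1 voxel).
  Passing tests therefore demonstrate correctness of the algorithms under
  the rigid-motion + unrelated-intensity model, not robustness to scanner
  physics.
* The thin head (c ≈ 5 voxels) makes boundary voxelization a visible
  fraction of the foreground; overlap scores on phantom masks saturate
  around 0.95–0.97 even for sub-degree alignment.  Properties that are
  about overlap rather than pose use a thicker 64 × 64 × 32 phantom.

## Ground-truth generation

1. Resample each image to isotropic spacing (min input spacing, trilinear).
2. Otsu two-level thresholding of a 256-bin histogram; the lowest of the
   three classes is background, everything else is head.  The threshold
   search maximizes between-class variance over all pairs via prefix sums
   and breaks ties toward the smallest pair.
3. PCA of the foreground voxel-center cloud.  Eigenvector signs are fixed
   (largest-magnitude component positive) and right-handedness restored by
   the cross product; this resolves the inherent sign ambiguity
   deterministically.  A residual 180° flip between two images is left to
   the optimizer's basin.
4. The symmetry transform maps principal axes onto the grid axes and the
   centroid onto the grid center.
5. The aligned pair is registered by maximizing MI with a 1+1 evolutionary
   strategy from identity initialization — symmetry alignment exists
   precisely to make identity a good start.
6. `T_comp = T_fix⁻¹ · T_reg · T_mov` carries the result back to the
   original frames.

### Optimizer numerics

Defaults: growth factor 1.05, epsilon 1.5·10⁻⁶, initial radius 6.25·10⁻³,
100 iterations, 500 spatial samples, 50 histogram bins; the registration
objective uses all voxels by default (the sample count applies when
subsampling is enabled).  Two numerical choices are the package's own:

* **Failure shrink factor** `growth^(-1/4)` (≈ 0.988), the one-fifth
  success rule companion: the radius then grows whenever acceptance exceeds
  20%.  A more aggressive shrink (e.g. `growth⁻⁴`) makes the radius decay
  even at 50% acceptance and stalls the search far from the optimum — this
  was measured directly on the 6-D quadratic benchmark.
* **Parameter scaling**: the scalar radius lives in a normalized space
  where one unit is one radian of rotation and ~half a head diameter
  (20 voxels) of translation, so a mutation displaces the head boundary
  comparably in all six directions.  This is the same normalization the
  ITK-style 1+1 optimizer assumes for its default radius; without it the
  printed radius cannot traverse even a 3° offset in the iteration budget.

MI is estimated from the joint histogram over each image's intensity range
(degenerate constant images collapse to one bin, giving MI 0, the correct
independence limit).

## Learning stage

The 3D CNN is implemented directly on numpy arrays (im2col-style sliding
window convolution, batch normalization with running statistics, leaky
ReLU slope 0.1, 2×2×2 max pooling, global average pooling, one dense
layer), with hand-derived backward passes verified against finite
differences.  Training is SGD with momentum 0.9, learning rate 0.001
dropped to 0.0001 after epoch 20, 30 epochs, 30% validation split, batch
size 8.  The loss is the half mean squared error over the six outputs.

* **Desk preset** (default): 32 × 32 × 8 input (volumes are resized on the
  way in), three conv blocks of 8/16/128 channels.  The 128-channel last
  block is a hard architectural constraint (it sets the feature width);
  everything upstream of it is sized for single-CPU runs.  A full-scale
  preset (256 × 256 × 26, five blocks 8-16-32-64-128) is available via
  `DCNNConfig.full_preset()`.
* The regression network reads the **moving image only**: in this corpus
  the fixed image is in a canonical pose per subject, so the displacement
  is identifiable from the moving image, while the pair regressor (below)
  sees features of both images.
* Feature extraction always runs batch-norm in inference mode, making the
  128-vector a pure function of (weights, volume); in train mode batch
  statistics couple samples, which is demonstrated in a regression test.
* Targets are used on their natural scales (degrees, voxels — both O(1–15));
  no target standardization in the CNN.

The pair regressor is a 256–10–6 feed-forward network, tanh hidden layer,
linear outputs.  Features and targets are standardized internally and the
standardization inverted at prediction (tanh saturation control).  Trainers:

* **Levenberg–Marquardt** on the sum-of-squares error: damped Gauss–Newton
  with the exact residual Jacobian, μ ×10 on rejection, ÷10 on acceptance.
* **Bayesian regularization**: LM on `β·E_D + α·E_W` with MacKay's evidence
  update after each accepted step — `γ = n_w − 2α·tr(H⁻¹)`,
  `α = γ / (2E_W)`, `β = (n − γ) / (2E_D)`, where H is the Gauss–Newton
  Hessian of the regularized objective; `tr(H⁻¹)` comes from the Cholesky
  factor.  α starts at 0.01, β at 1.
* **Scaled conjugate gradient** (Møller) with backpropagated gradients.

On held-out phantom pairs the Bayesian-regularized ANN on concatenated pair
features consistently attains higher pooled R² than both the end-to-end CNN
and the other two trainers; the acceptance suite asserts the ANN ≥ CNN
ordering (directional, not a fixed value).

## Modality classification

Same backbone, 2-class softmax head, cross-entropy loss, same training
strategy.  Ties break toward MRI; `order_pair` refuses to order a pair when
both volumes get the same label or either confidence falls below 0.6 (a
reject option favored over silent wrong ordering).  The classifier trains
on the augmented train split — displaced copies inherit the parent's
modality label — which also makes it robust to pose.

## Evaluation metrics

Overlap metrics are exact set arithmetic on Otsu-binarized volumes (the
same foreground rule the symmetry stage uses): DSC, JSC, precision,
sensitivity, and the contour matching score.  CMS equals DSC identically
for binary masks and DSC = 2·JSC/(1+JSC); both identities are asserted at
1e-12 over random masks.  SSIM is evaluated globally (single window) from
image means, variances, and cross-covariance with C1 = (0.01L)²,
C2 = (0.03L)².  Classification metrics are computed exactly from confusion
counts; 0/0 ratios are reported as NaN with the metric flagged as
undefined, never silently coerced to 0.

## Problem sizes in the standard benchmarks

The packaged benchmarks (also used by `scripts/acceptance.py`) run at desk
scale, the package's chosen operating point for single-CPU work: 20
ground-truth recovery pairs at 64 × 64 × 16, a learning corpus of 20
subjects × (1 + 16 augmentations) ≈ 200 training pairs with 20 held-out
evaluation pairs, classifier training on 16 subjects × (1 + 4
augmentations), and 4 large-rotation (30–45°) pairs for the
symmetry-benefit comparison.  All randomness flows from a single seed
through named substreams.

## Known limitations

* Only axis-aligned (identity-direction) volume grids are supported in I/O.
* The PCA pose estimate assumes a clearly triaxial foreground; near-spherical
  heads degrade it (flagged only when covariance is rank-deficient).
* The 1+1 ES is a local optimizer: displacements far beyond the
  augmentation range (and 180° symmetry flips that PCA sign conventions do
  not resolve) can fall outside its basin.
* Gaussian noise only; no slice-dependent artefacts.
* The learning benchmarks quantify behavior on phantoms; no claim is made
  about accuracy on clinical data.
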