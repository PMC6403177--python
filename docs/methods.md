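# Methods

This note documents the models and procedures implemented in
`vesselseg`, the defaults and why they are set where they are, and what
the synthetic validation does and does not establish.

## Problem setting

Input is a 3D angiographic intensity volume with a precomputed binary
brain mask (the product of skull stripping) and, for training and
evaluation, a binary vessel label volume. All computation happens in
0-based voxel-index space; distances are reported in isotropic voxel
units and the NIfTI affine is only carried through for visualization.
Vessels occupy roughly 0.9% of brain voxels, and the whole design —
balanced sampling, the Dice-type loss, the distance-based metrics —
follows from that imbalance and from vessels being thin, bright,
elongated structures.

## Synthetic phantoms

The generator emulates the statistics the pipeline assumes rather than
vascular anatomy:

* **Brain mask**: an axis-aligned ellipsoid at 90% of the grid extents —
  the simplest shape with a genuine interior/exterior distinction.
* **Centerlines**: cubic splines through 5 jittered waypoints started
  at a random interior point with a random, gradually bending heading;
  a curve that leaves a radius-shrunken ellipsoid is rejected and
  redrawn, and a bounded retry budget turns unsatisfiable geometry into
  an explicit placement error.
* **Tubes**: each centerline is rasterized at ~0.5-voxel steps with a
  radius drawn from `radius_range` (default 1–3 voxels) and, by
  default, a linear taper to 60% toward the distal end, giving
  small-vessel-like endings.
* **Prevalence control**: a deterministic 14-step bisection on a global
  radius scale (clipped to `radius_range`) drives the labeled fraction
  of brain voxels to `target_vessel_fraction` (default 0.009). Across
  seeds the realized fraction stays within a few tenths of a percent
  of the target; the radius clip bounds what is reachable and a missed
  target is logged.
* **Intensities**: class mean (vessel 200, background 100, arbitrary
  units — a ~2:1 contrast typical of masked TOF tissue) multiplied by a
  smooth multiplicative bias field (Gaussian-filtered noise scaled to
  ±20%) plus additive Gaussian noise (σ = 15). A Rician option models
  magnitude-image noise; the Gaussian default keeps test statistics
  analytic.

Everything is reproducible bitwise from the seed. The phantoms do *not*
model flow artifacts, skull/scalp anatomy, vessel bifurcations, signal
dropout in stenoses, or pathology; consequently, passing the end-to-end
tests shows the pipeline's machinery is correct and can learn bright
tubular structure at realistic prevalence — it does not certify
performance on patient data.

## Balanced patch sampling

Per subject the sampler draws, from axial slices, `n_vessel` patches
whose central voxel (offset `(P//2, P//2)`; the even-size center must be
fixed by convention) is labeled and `n_background` whose central voxel
is not (defaults 500/500, patch sizes 16/32/64/96). "Background-
centered" deliberately permits vessels elsewhere in the patch — these
are the hard negatives near boundaries. Background centers are
restricted to the brain mask so patches come from tissue. Draws are
uniform without replacement; a class whose eligible set is smaller than
requested is sampled with replacement and logged, and an empty eligible
set with a positive request raises. Patches are standardized to zero
mean and unit population variance; a patch with standard deviation
below 1e-8 maps to all zeros.

## Network and training

The U-net encoder applies on 4 levels two padded 3×3/stride-1
convolutions (ReLU after each, dropout after the first) followed by
2×2/stride-2 max-pooling, doubling channels at each descent from the
base width; the bottom level is two further convolutions; the decoder
mirrors this with 2× up-sampling, concatenation of the encoder skip,
and two convolutions; a final 1×1 convolution plus sigmoid yields
per-pixel probabilities. All convolutions carry biases; there is no
batch normalization.

The decoder's up-sampling is a **parameter-free nearest-neighbor
repetition**. This choice is pinned by parameter accounting: the
schedule yields exactly 31,377,793 trainable parameters at base width
64 and 7,846,081 at base width 32, whereas learned 2×2 up-convolutions
would yield 31,030,593 for the full net. `count_parameters` exposes
both closed forms and the test suite asserts the built model matches.

Training minimizes `1 − D` with the Laplace-smoothed soft-Dice `D`
(s = 1) per batch, using the exact analytic gradient of the smoothed
coefficient (verified against central finite differences to 1e-5
relative; the widely quoted V-net gradient expression is its s → 0
limit). Weights are Glorot-uniform initialized with convolutional fans
(`fan = C·k²`); Adam runs with default moments (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8) and only the learning rate varies. Augmentation composes
random horizontal/vertical flips (p = 0.5 each), rotation uniform in
±30°, and shear uniform in ±10° — ranges chosen as the conventional
mild-geometric-augmentation regime — applied jointly to image
(bilinear, edge-replicate) and label (nearest-neighbor, re-binarized),
on the fly per epoch. Epoch count is config-driven with an optional
best-validation-Dice checkpoint. Batch order, augmentation draws,
dropout masks and initialization all derive from one seed, making
training bit-reproducible at fixed thread configuration.

The per-architecture, per-target-metric hyperparameter presets
(learning rate / batch size / dropout; see `vesselseg.nn.PRESETS`) are
exposed by name, e.g. `preset_config("half_unet", "dice")` → lr 1e-4,
batch 64, dropout 0.1.

The engine itself is NumPy: im2col convolutions backed by BLAS matrix
products, explicit backward passes for every layer. This keeps the
dependency surface minimal and every gradient inspectable; it is CPU
code, so the published full-size configuration trains slowly, and the
validation suite exercises scaled-down instances instead (below).

## Reconstruction

Each slice is symmetrically zero-padded to the stride grid, tiled into
P×P windows (default stride = P, i.e. non-overlapping, matching the
training patch statistics; stride P/2 with mean-averaging of overlaps
is available), each window standardized exactly as in training,
predicted, stitched, cropped, masked, and thresholded at probability
0.5. Windows that do not intersect the brain mask are skipped and
contribute zero probability. For any window-independent (voxel-wise)
predictor, tiled reconstruction with normalization disabled equals
direct application exactly, for any stride ≤ P — the stitching-identity
contract the tests enforce.

## Evaluation metrics

Dice is computed from exhaustive voxel confusion counts; by convention
two empty masks score 1.0 (nothing to find, nothing found). 95HD and
AVD are computed between the full voxel point sets (no surface
extraction) via the Euclidean distance transform of each mask's
complement, which is exactly the all-pairs nearest-neighbor distance;
percentiles interpolate linearly between order statistics.
Symmetrization takes the maximum of the two directed statistics (the
Hausdorff construction); mean-of-directions is available as an option.
Empty masks raise rather than return sentinels so cohort averages are
never silently contaminated. Error maps code TN/TP/FP/FN as 0/1/2/3,
and their histogram equals the confusion counts by construction.

## Graph-cut baseline

The baseline poses binary labeling of a slice as an MRF energy with a
uniform pairwise cost `w` per disagreeing 4-neighbor pair (published
setting `w = 10`) and solves it exactly as a minimum s–t cut. The data
term — not pinned by any published description — is the simplest
MAP-consistent construction for bright-vessel imagery: with `u` the
min-max-normalized slice intensity, labeling a pixel vessel costs
`−log(u+ε)` and background `−log(1−u+ε)` (ε = 1e-6, clipped to
nonnegative); out-of-mask pixels get a pseudo-infinite background
attachment. The construction is isolated behind `unary_capacities` so
alternatives can be swapped. In patch mode, tiling partitions only the
minimum-cut problem; the intensity normalization stays slice-level, so
the two modes agree except at tile seams.

Capacities are quantized to integers (factor 1e6) for the max-flow
solver (`scipy.sparse.csgraph.maximum_flow`); the quantization
perturbs energies by ~1e-6 per term, far below the energy gaps of
non-degenerate instances, and the exhaustive-enumeration tests confirm
the returned labelings attain the exact real-valued minimum on small
grids. The cut is recovered by residual-graph reachability from the
source, whose side is the vessel class.

Two behaviors of this baseline are worth knowing. First, per-slice
min-max normalization makes slices *without* vessels pathological: the
noise is stretched to the full [0,1] range and roughly half of the
pixels look "bright", producing salt-and-pepper false positives at low
`w`. Second, at the published `w = 10` the pairwise term dominates the
weak intensity evidence of tubes only 1–2 voxels thick, and the
phantom's vessels are erased entirely. Both are intrinsic to an
intensity-only data term on thin structures — precisely the weakness
the learned model addresses — so on phantoms the baseline is
informative for its *ordering* below the U-net, not for its absolute
Dice.

## Scaled-down validation sizes

The suite's end-to-end run trains the half architecture at base width 8
on 2,000 balanced 32×32 patches from 8 phantom subjects (64³), using
lr 1e-3 for 8 epochs — a configuration chosen so a single-CPU run
completes in minutes — then reconstructs 2 held-out phantoms, where it
reaches Dice > 0.95 against ground truth and strictly exceeds the
graph-cut baseline. The overfit check (10 patches, 200 epochs) and the
loss-decrease smoke test run at base width 4 on 16×16 patches.

## Known limitations

* CPU-only training; the full-size published configurations are
  buildable and countable but impractically slow to train here.
* 2D patches only; no 2.5D/3D context, no vessel-tree post-processing
  or connectivity enforcement.
* Phantom realism limits (above): results on phantoms bound machinery
  correctness, not clinical performance.
* The graph-cut data term is intensity-only; no learned or
  histogram-based likelihoods.
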