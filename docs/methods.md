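# Methods

## The problem

OCT angiography (OCTA) images retinal blood flow as a 3-D volume. The
retinal vasculature is organised into a superficial plexus of large bright
vessels, a deep plexus of fine capillary mesh, and an avascular outer
retina. Classical plexus segmentation projects the OCTA volume between
layer boundaries taken from the *structural* OCT scan; those boundaries
are unreliable exactly where pathology matters. This package implements an
OCTA-only alternative: a convolutional segmenter is trained on weakly
labeled en face slab projections (each projection carries one whole-image
class label inherited from the slab that produced it) plus synthetic
two-class blends, and is then run over thin slabs spanning the whole
retina, whose per-slab predictions are reassembled into a per-voxel labeled
cube.

Because the clinical dataset behind the method is not public, the package
ships a phantom generator that reproduces the *texture statistics* the
method relies on, so every stage is exercisable and testable end to end.

## Phantom OCTA volumes

A phantom cube is three depth-ordered zones between four smooth boundary
surfaces (ILM, superficial/deep junction, deep/avascular junction, RPE),
placed at canonical fractional depths (0.14/0.36/0.58/0.82 of the axial
range) and perturbed by low-frequency random fields (amplitude 3.5% of the
depth). Zone textures:

- **superficial** — persistent random walks dilated to ~3-px calibre
  (value ≈ 245) over a smooth background (≈ 100 ± 8): sparse, bright,
  curvilinear large vessels;
- **deep** — band-pass filtered Gaussian noise (pass band σ 0.8–2.5 px)
  scaled to mean 85, amplitude 45, clipped to [20, 160]: a fine capillary
  mesh;
- **avascular** — low-amplitude speckle (mean 14, clipped below 100).

Per-voxel Gaussian noise (σ 5) is added throughout, and the mean-intensity
ordering superficial > deep > avascular holds by construction. The recipe
values were chosen once so that a linear classifier on the (mean,
variance) of 16×16 patches separates the three textures with ≥ 95%
accuracy — the condition that makes the downstream desk-scale learning
problem well posed — and are verified by a test, not tuned per run.

The projection artifact of OCTA ("tails" of superficial vessels echoing at
deeper depths) is emulated by adding the superficial vessel map into the
deep zone attenuated by 0.4 (configurable, on by default). A generic
disease perturbation (a dome-shaped distortion pushing all four surfaces
outward) stands in for the heterogeneous pathologies of a clinic
population; the healthy fraction defaults to 14/33.

What the phantoms do **not** model: OCT speckle statistics and signal
formation, vessel connectivity across depth, the foveal avascular zone,
real pathology morphology, and instrument layer-segmentation errors
(phantoms carry exact ground-truth boundaries). Passing tests therefore
demonstrate that the pipeline's machinery is correct and that the method's
comparative claims hold under controlled texture statistics — not clinical
performance.

## Dataset construction

**Single-class images.** Each zone is max-projected between its boundary
surfaces (closed interval: integer depths z with upper ≤ z ≤ lower; where
a sub-voxel interval contains no integer depth the nearest voxel is used).
The deep and avascular projections are cleaned of tails by subtracting
0.4 × the superficial projection, clamped at zero — a declared stand-in
for the instrument's unpublished removal algorithm, with the subtraction
scale matched to the phantom tail attenuation. Three images per cube; with
normalization copies, six.

**Percentile normalization.** The bottom 2% of pixel values map to 0, the
top 1% to 255, the central band rescales linearly (percentiles by linear
interpolation; ties at the cut clip outward; 8-bit rounding half away from
zero). Constant images pass through with a warning, since phantom
avascular slabs can be nearly constant after tail removal. Normalization
makes the class-conditional histograms converge, which removes the trivial
brightness shortcut a classifier could exploit.

**Two-class blends.** For each cube, four blends pair adjacent classes
(superficial→deep, deep→superficial, deep→avascular, avascular→deep): a
random ellipse (area fraction drawn from [0.05, 0.25], aspect up to 2.5,
random rotation, strictly interior) is smoothed with a Gaussian of width
drawn from [2, 6] px at 256-px scale (scaled to the image size), then
clamped so weights ≥ 0.995 become exactly 1 and ≤ 0.005 exactly 0 — a full
transition from 100% majority to a 100% minority core. The blended image
is the per-pixel convex combination; the binary target thresholds the
weights at 0.5 (ties to the minority). Each pairing draws an independent
mask. With normalized sources repeated, eight blends per cube.

**Thin slabs.** The ILM→RPE subvolume is decomposed into slabs whose
center depths interpolate linearly from the ILM contour to the RPE
contour; each slab pixel averages a 5-voxel axial window (half-width 2).
The default slab count, ceil(median retinal thickness / 3), makes
consecutive windows overlap by ~2 voxels, so every retinal voxel is
covered at least once; the count and stride were left open in the original
design, and overlap is the choice that makes voxel-level voting
meaningful. A volume-based tail removal (subtract α × the superficial-zone
maximum from all deeper voxels, clamp at 0) is available before slab
construction.

## Patient-level splitting

Patients, not cubes, are assigned to train/validation/test so no eye ever
spans a boundary. The splitter is a seeded constrained randomization:
patients ordered by descending cube count are dealt round-robin (ties
shuffled), which spreads cube-rich patients across groups; draws violating
eye balance (both eyes per group) or health balance (healthy and diseased
patients per group) are redrawn. The original study partitioned manually;
constrained randomization reproduces the stated criteria reproducibly.
For small demonstration cohorts the balance constraints can be
unsatisfiable (one single-eye patient alone in a group); the default
`auto` mode then relaxes them with a logged warning, while
`require_balance=True` raises instead. Training patients are additionally
tagged into 4 sub-groups, recorded in the manifest but consumed as their
union. Group cube-count percentages are reported, not enforced.

## The segmenter

A single-channel image enters a learned 1×1 convolution (1→3 channels),
then an encoder–decoder with skip connections: `unet_like` merges decoder
and encoder features by channel concatenation, `linknet_like` by addition.
The head is a 1×1 convolution to 3 per-pixel logits under softmax. Two
scales exist: `tiny` (base 8 channels, 2 pooling stages, ≈ 22k / 19k
parameters for the two merge styles) and `paper` (base 32, 4 stages,
several million parameters, constructible but not exercised by default).
Activations are leaky rectifiers (slope 0.1): at these parameter counts a
fully dead rectified path can permanently silence one class's logit — an
unlucky initialization then trains to a zero-Dice class collapse — and
the leak removes that failure mode. The network, its backward pass, and
Adam are implemented in NumPy (channels-last im2col convolutions);
training is single-threaded, bit-deterministic for a given seed.

Training minimizes per-pixel categorical cross-entropy with Adam at a
maximum learning rate of 1e-4 (constant by default; a one-cycle option is
provided since "maximum learning rate" leaves the schedule open), batch
32. Augmentation applies independent horizontal/vertical flips and a
rotation up to ±45° followed by a center crop to the largest inscribed
axis-aligned square (minus a 2-px interpolation guard) and a resize back,
which zooms slightly; label maps follow the identical transform with
nearest-neighbor interpolation. Single-class images contribute
whole-image one-class targets; two-class samples contribute their binary
targets; the loss is unweighted. The checkpoint with the best validation
loss is kept. Inputs larger than the model size are downsampled by exact
area averaging (masks by nearest neighbor); predictions are mapped back to
the source resolution by nearest neighbor.

## Whole-cube inference

Each thin slab is predicted independently; its per-pixel class
distribution is deposited onto every voxel of the slab's 5-voxel averaging
window. Per voxel, the deposited distributions are summed and the argmax
class assigned — probability-mass voting, chosen over majority-of-argmax
because it uses the full distributions and reduces ties; remaining ties
resolve deterministically to the anatomically shallower class. Voxels
outside [ILM, RPE] are cropped to an `outside_roi` code after voting.
B-scan slices render the flow image with a semi-transparent class-colored
overlay.

## Evaluation

Dice = 2|A∩B|/(|A|+|B|) per class, one-vs-rest from the argmax map.
Per-image scores average uniformly over images (not pixel-pooled). A class
is scored on an image only when the image's ground truth contains it;
stray predicted pixels of an absent class are charged to the present
classes (whose masks those pixels are missing from) rather than producing
a hard zero for the absent class. The alternative — scoring a
predicted-but-absent class as 0 — makes published per-class averages of
the form 0.9995 on single-class test sets unattainable whenever even one
stray pixel appears anywhere, so the truth-presence convention is the one
consistent with reported score tables. The empty-empty comparison is
defined as 1.0. The report mirrors
the study's table layout: per-class Dice and their mean for the
single-class and two-class test sets, plus the combined simple average
(mean of the two set means).

## The desk-scale study

`octaplex.experiments` runs the whole protocol: a 15-patient cohort (1–2
cubes each, 64×64×96 voxels, cohort seed 42), a 60/20/20 patient split,
raw (non-normalized) single-class and two-class training images, the
`linknet_like` tiny network at base width 6 (the merge style that
performed best at full scale), and 300 epochs at batch 32 and maximum
learning rate 1e-4 under a one-cycle schedule. These sizes are the
package's study conditions, chosen so a full train-and-evaluate pass takes
minutes on one CPU; the epoch budget stays well under the 2400 epochs of
the full-scale regime because the phantom task is far smaller.

Two full-scale ingredients are deliberately off at desk scale, with the
operators themselves implemented and tested:

- **Geometric augmentation.** Flips and rotate-crop exist to multiply
  scarce clinical data and enforce orientation invariance. The phantom
  study has abundant, orientation-free synthetic data, and at 64 px the
  rotation's interpolation resampling blurs textures enough to cost
  boundary localization at evaluation time, where images are unblurred.
  `TrainConfig(augment=True)` restores it (and is the default outside the
  desk-scale protocol).
- **Normalized image copies in the training mix.** Percentile
  normalization combats the brightness shortcut of clinical data; the
  phantom textures are themselves the signal of interest. The normalized
  copies are constructed, verified and counted by the dataset ops.

`scripts/acceptance.py` reruns this study from scratch: the per-cube
two-class construction counts (raw and with normalized sources), then both
dataset mixes trained over three seeds each, reporting the median combined
simple-average Dice for the combined mix and for the single-class-only
mix. The comparative pattern — combined-mix training beats
single-class-only training, most visibly on two-class test images — is the
method's central claim and is asserted by the acceptance tests at phantom
scale.

## Numerical choices and edge cases

- Depth intervals for projection are closed; zone voxel sets are disjoint
  (a voxel belongs to the zone whose half-open depth interval contains it).
- Center depths and 8-bit quantization round half away from zero.
- Averaging windows clamp at the volume edges (mean over available
  voxels); deposition during reassembly clamps identically.
- Degenerate normalization (zero intensity range) passes through with a
  warning rather than erroring.
- Blend masks that cannot fit an interior saturated core resample a
  bounded number of times, then raise.
- Seeds: every stochastic component takes a `numpy` Generator or an
  integer seed; cohort generation spawns per-cube seed sequences so cube
  identity is stable under cohort-size changes.

## Known limitations

- Phantom realism is bounded to texture statistics; no claim about
  clinical Dice transfers from these tests.
- The tiny network's receptive field (~20 px) suits 64-px phantoms;
  128-px phantoms train proportionally slower.
- The projection-removal operators are declared stand-ins; the
  instrument's actual algorithm is unpublished.
- Training at `paper` scale (pretrained DenseNet depth, 2400 epochs) is
  out of scope by design; the architecture is constructible for
  inspection only.
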