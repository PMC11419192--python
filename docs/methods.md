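# Methods

## Problem and approach

Cherenkov imaging during radiotherapy shows patient-specific dark
bio-morphological structures — chiefly subcutaneous veins — inside the
bright beam footprint on the skin. Segmenting these structures enables
position verification and motion monitoring, but annotated Cherenkov data
are scarce and the images have low signal-to-noise ratio. `cherenseg`
implements the standard remedy: transfer learning from a data-rich,
morphologically similar source domain. A residual encoder–decoder network
is pretrained on high-contrast retinal-vessel-style patches and fine-tuned
on a small set of Cherenkov-style patches. Formally, with source domain
D_S and target domain D_T sharing the binary segmentation task, the model
f_T minimizing E_{(x,y)~D_T}[ℓ(f_T(x), y)] is obtained by initializing
from the source-trained f_S and continuing optimization of all parameters
on D_T.

## Synthetic phantoms

Clinical Cherenkov data are IRB-restricted, and the fundus dataset used at
full scale is an external download, so every stage is exercised on
synthetic vascular phantoms:

- **Vessel trees** grow as biased random walks with per-generation
  bifurcation: each segment walks `n_steps` steps of length `step` with
  Gaussian heading jitter, then bifurcates with probability `branch_prob`
  up to `depth` generations; child widths shrink by a factor 0.78. This
  reproduces curvilinear branching morphology cheaply; it makes no claim
  to hemodynamic realism. Default growth parameters (depth 7, branching
  0.9, widths 4–8 px at 448 px frames) were set so the vessel-pixel
  density is ~8 %, the regime in which the 5 % patch-retention filter
  keeps most central patches, as it does on real fundus data.
- **Source domain** renders the tree dark (contrast 0.7) on a bright
  background (0.85) with light noise (sigma 0.02) — a grayscale stand-in
  for fundus photographs.
- **Target domain** renders low contrast (0.35) and heavy noise
  (sigma 0.12) and confines all signal to a superelliptic bright beam
  footprint, as in Cherenkov images; the ground-truth mask is restricted
  to the beam because vessels outside it are invisible in the signal and
  labeling them would make the synthetic task ill-posed. No published
  quantitative noise characterization of Cherenkov images exists, so the
  target noise level is a package choice, not a measured value.
- **Video** renders independent-noise frames at 19.6 fps, the Cherenkov
  camera frame rate. Free-breathing (FB) streams displace the centerlines
  by a sinusoid (amplitude in px, period in seconds) before rasterization
  — no interpolation artifacts; amplitude 0 is the breath-hold (DIBH)
  regime. For the gate-sweep protocol the per-frame noise (sigma 0.45
  against contrast 0.3) exceeds the vessel contrast so that single
  frames are barely segmentable and SNR must be bought by cumulation,
  which is the operating regime of raw Cherenkov video.

Coordinates are row-major, 0-based (row, col). Images are clipped to
[0, 1] after noise addition; at extreme noise this biases the empirical
moments, which is why the moment tests use mid-range backgrounds.

What the phantoms do **not** model: color fundus appearance, Poisson shot
noise and camera-intensifier statistics, skin texture, scars/pigmentation,
non-rigid deformation. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that transfer helps under controlled
domain shift, not that clinical accuracy numbers are reproduced.

## Dataset construction

Images are cropped to a centered square ROI of side N x 224 (N = 6 for
fundus-scale frames giving 36 patches; Cherenkov beam ROIs use N <= 4,
with an explicit per-image center available instead of reimplementing the
manual ROI choice), tiled without overlap in row-major order, and filtered
so only patches whose labeled area *strictly exceeds* 5 % of the patch are
retained ("exceeded", hence strict inequality; the boundary case is
integer-checked at 2509/50176). The retained pool is split 90/10 into
train/validation by a seeded permutation; the train count is
round-half-up since realistic patch counts are not multiples of 10.

Training-time augmentation applies three *independent* events per patch
and epoch: horizontal flip (p = 0.33), rotation by 90/180/270 degrees
(p = 0.33, exact pixel permutations applied to image and mask alike), and
additive Gaussian noise on the image only (p = 0.50) with sigma drawn
uniformly up to 25 % of the dynamic range ("maximum magnitude" read as a
sigma bound — the conventional reading; configurable). Augmentation is
redrawn every epoch rather than pre-materialized.

## Network

A 2-D SegResNet-family backbone: pre-activation residual blocks
(batch norm → ReLU → 3x3 conv, twice, plus an additive identity skip),
encoder block counts [1, 2, 2, 4] over four spatial levels with 32
initial filters doubling per level, strided-conv x2 downsampling, and a
symmetric decoder with a single block per level, 1x1 channel reduction
followed by nearest-neighbour x2 upsampling and additive encoder skips.
A 1x1 single-channel head with a sigmoid yields the probability map; an
interior softmax would be degenerate on one channel and is not used.
Downsampling by strided convolution and ReLU nonlinearity are backbone
conventions; both are exposed in `NetworkConfig` (`use_residual` provides
an ablation switch). Inputs are intensities in [0, 1]; no z-scoring.

The forward pass, backpropagation, RMSProp and parameter management are
implemented directly on numpy arrays (im2col + BLAS matmul convolutions).
Parameters default to float32 — the conv lowering is memory-bound, so
this nearly halves step time — with float64 available and used by the
finite-difference gradient tests, which verify every layer's backward
pass to ~1e-5 relative error.

## Objective and training

L = λ1·L_Dice + λ2·L_CE on sigmoid probabilities, with λ1 = 1, λ2 = 0.1
(the weighting reported to train best). Dice loss uses smoothing
ε = 1e-5 in numerator and denominator and batch-mean reduction;
cross-entropy is binary (single sigmoid channel), clipped by δ = 1e-7
before the logarithm. A per-class weight hook exists and defaults to 1.

Full-scale defaults: batch 24, RMSProp (ρ = 0.9, eps = 1e-8), learning
rate 1e-5, 400 pretraining epochs with 1e-8 L2 weight decay, 100
fine-tuning epochs without decay, all parameters trainable during
fine-tuning (no freezing). Each stage records the validation loss before
the first update (epoch 0) and after every epoch, and returns the
checkpoint at the argmin — so a warm start that fine-tuning never
improves on remains selectable; the argmin rule is applied to both stages
symmetrically. The sequential pretrain→fine-tune procedure is the primary
path; a single-stage joint mode with a convex source/target mixing weight
exists as an experimental flag (default off) because the sketched joint
variant leaves its transfer rate undefined — the mixing weight is an
extrapolation, not an established semantics.

## Evaluation

Dice (2|A∩B|/(|A|+|B|)), IoU (|A∩B|/|A∪B|), and boundary IoU: each mask
intersected with the band of its pixels within Euclidean distance d of
its contour (image borders count as contour; default d = 2 px — the
width used in published boundary-IoU practice; both d and the distance
metric are configurable, and results are internally comparable but not
guaranteed to match any particular published band choice). Two empty
masks score 1 (perfect agreement on absence); empty vs non-empty scores
0. Largest-connected-component extraction defaults to 8-connectivity
(vessels are thin diagonal structures), with size ties broken by the
smallest row-major origin.

**Robustness protocol**: the binarized prediction on the original image
is the reference; the image is rotated 90/180 degrees or corrupted with
Gaussian noise (sigma = 0.10 of range), re-segmented, the rotation is
inverted on the predicted mask (comparison is meaningless otherwise),
both masks are reduced to their largest component (configurable, default
on), and Dice is computed.

**Sub-cumulative protocol**: frames are averaged over disjoint
consecutive k-frame windows (disjoint, for independent standard errors;
averaging rather than summing keeps the intensity scale gate-invariant,
and the result is min-max rescaled), k/19.6 s per gate. The prediction
on the full cumulation is the reference; per-gate mean Dice and standard
error are reported, and full masks (not largest components) are compared
by default. A `reference="truth"` mode scores against the ground-truth
rest mask instead — required when comparing FB vs DIBH at the full gate,
where the prediction reference would be compared to itself.

## Scaled benchmark and problem sizes

The transfer-benefit benchmark runs, per seed: 200 source patches and 20
target patches of 64 x 64 px (2 x 2 grids of 128-px phantoms, retention-
filtered), a 2-level 8-filter network, 30 pretraining epochs, 30
fine-tuning epochs, and an identically-seeded scratch model trained 30
epochs on the target alone; the selected checkpoints' validation Dice
are compared over 5 seeds. At ~250 optimizer steps the full-scale
learning rate of 1e-5 cannot move RMSProp-normalized weights measurably,
so the benchmark uses 1e-3; the filter width and rate are the scaled
study conditions, chosen once, while 1e-5/batch-24 remain the full-scale
defaults. The benchmark takes roughly ten minutes on one CPU core;
robustness and gate-sweep protocols run on 96-px phantoms and 120-frame
streams in seconds.

## Known limitations

- The phantom generator's realism gap (above) bounds what the benchmark
  demonstrates about clinical data.
- The engine is CPU-only; full-scale training (20k patches x 400 epochs)
  is intended for the published hyperparameters but is not practical
  without accelerator hardware.
- Boundary-IoU band width is a convention, not a calibrated match to any
  external report.
- Bitwise reproducibility holds per platform/BLAS; across platforms,
  loss traces agree only to float32 rounding.
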