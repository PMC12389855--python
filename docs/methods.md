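# Methods

## The problem

A pressure-sensitive exercise mat reports a 2-D grid of normal pressure
(kPa) at 60 Hz. The frames are sparse — only the body parts touching the
mat leave a signal — and noisy: broadband sensor noise plus occasional
small spurious blobs from capacitive interference. The package implements
a two-stage pipeline: **Stage 1** restores the clean pressure map from a
corrupted frame with a dual forward-diffusion model, and **Stage 2**
regresses the 3-D positions (mm) of 12 body keypoints from the restored
frame with a transformer–convolution network. A synthetic-scene generator
stands in for the physical mat and a motion-capture rig, so the whole
pipeline is trainable and testable from code alone.

## Synthetic tactile scenes

A 12-joint stick body (head, pelvis, shoulders, elbows, hands, knees,
feet) is posed for one of eight activities (standing, wide stance, bend,
squat, plank, push-up, lunge, sit). Activity layouts are written in
fractions of the body *span* (torso + leg length), so one repertoire
renders consistently on the full 45 x 16-tactel mat (1.80 m x 0.64 m,
40 mm pitch) and on the desk-scale two-module patch (16 x 8 tactels,
0.64 m x 0.32 m) used throughout the tests. Joints in ground contact sit
exactly on the mat plane z = 0.

Each contact joint deposits an isotropic Gaussian pressure blob at its mat
projection (sigma 60 mm full-scale, 75 mm on the desk patch where the body
is scaled by 0.45). Blob amplitude is 12 kPa for a 70 kg body standing on
two contacts, shared across contacts and scaled linearly with body weight,
then clipped at the 15 kPa sensor ceiling. 12 kPa peak heel pressure
leaves a wide margin above the corruption noise while staying below the
ceiling; linearity in weight and translation equivariance are exact by
construction and are asserted as properties.

Corruption follows the additive model *P = P_true + N*: zero-mean Gaussian
noise (default sigma 1.0 kPa) plus a Poisson-distributed count (mean 3 per
frame) of small spurious blobs with 3 x 3-pixel support, clipped to
[0, 15] kPa. The noise level was fixed so that a corrupted frame scores in
the low-to-mid 20s dB PSNR against its clean counterpart — the regime
where published restoration baselines for this kind of data operate, and
where restoration has measurable headroom. The spurious blobs are
deliberately smaller than the 5 x 5 opening kernel of the mask stage, so
the refined mask provably excludes them; this is what makes the mask
stream informative. What the generator does **not** model: soft-tissue
contact mechanics (real footprints are not Gaussian), load redistribution
within a pose, temporal correlation of noise, sensor drift, and the
two-layer (area + pressure) channel structure of the real mat. Passing
tests therefore demonstrate the pipeline's mechanics and its behaviour
under this noise model, not performance on real recordings.

Datasets cycle frames through the activity list at 60 Hz; frames and poses
are paired by exact timestamp. Two whole activities (sit, squat) are held
out as the validation split; the remaining frames are split 80/20 into
train and test, mirroring an activity-disjoint evaluation protocol.

## Stage 1: dual-diffusion signal enhancement

Two synchronized forward diffusion processes share one noise schedule but
draw independent noise: one noising chain on the pressure frame, one on
the refined binary mask (which becomes a soft mask as noise accumulates).
The per-step factor alpha_t decays linearly from `alpha_start` (t = 1) to
`alpha_end` (t = D). Both the printed recursion
x_t = alpha_t x_{t-1} + sqrt(1 - alpha_t) eps ("paper_literal") and the
standard variance-preserving form
x_t = sqrt(alpha_t) x_{t-1} + sqrt(1 - alpha_t) eps are implemented; the
default is variance-preserving, which keeps unit-variance signals at unit
variance for every t (asserted as a property). Closed-form marginals
(scale and variance of x_t given x_0, obtained by unrolling the
recursion) are exposed in `diffusion.marginal_stats` and verified by
Monte-Carlo in the tests.

The generic schedule default is D = 50 with alpha from 0.999 to 0.95. The
desk preset uses D = 10 with alpha 0.999 to 0.99: with ten steps the
gentler endpoint keeps the per-step noise increment comparable, and the
round trip (noising the observation to step D, then walking back) does not
drown the frame in more noise than the restoration problem itself
contains.

### Refined mask

The mask is thresholded from the raw input frame and cleaned by a
morphological opening: three binary erosions followed by three dilations
with a solid 5 x 5 square, outside-frame pixels counting as background.
Any component whose extent is under 13 pixels in either direction cannot
survive three 5 x 5 erosions; the generator's spurious blobs (3 x 3) are
therefore removed exactly, while desk-scale foot blobs (roughly 18 x 22
pixels above threshold) survive. The default threshold is Otsu's method
on the nonzero pixels — parameter-free, but its split point moves with
the noise histogram — so the desk preset pins the absolute override at
3.0 kPa, three standard deviations of the sensor noise.

### CDA layer and U-Net

The contour detection and alignment layer sits at the U-Net entrance.
Both single-channel inputs (diffused pressure, diffused soft mask) are
lifted by 1 x 1 stems; a sinusoidal embedding of the step index t,
passed through a small-initialised linear projection, is added to both
stems (small initialisation keeps the O(1) embedding from swamping the
O(0.1) signal early in training). The mask stream is expanded by
pyramidal pooling — parallel 3 x 3 atrous convolutions at rates 2, 4, 6,
8 with same-padding, concatenated and projected back — and fused into the
pressure stream by multi-head cross-attention whose queries are pressure
pixels and whose keys/values are non-overlapping average-pooled mask
tokens. The attention output is residual-added to the pressure stream.
The fused map feeds a standard symmetric U-Net (double-conv blocks,
average-pool downsampling, 2 x 2 stride-2 transposed-convolution
upsampling, skip concatenation), padded and cropped when the frame does
not divide 2^depth.

### Training and the reverse walk

The network predicts the less-noisy signal directly (not the noise). For
each training sample a step t is drawn; the input pair is sampled from
the closed-form forward marginal of the *noisy* frame and of its refined
mask at step t, and the regression target is the marginal **mean** of the
*clean* frame at t - 1 — a deterministic target, which trains far better
at small scale than a stochastic sample of the clean trajectory. A learned
residual path feeds the input frame to the output scaled by the per-step
marginal ratio, so the U-Net regresses only the correction. Step losses
are weighted by inverse marginal variance: the low-t steps decide the
final reconstruction and deserve the precision. Adam (lr 5e-3 default,
betas 0.9/0.999) with global gradient-norm clipping at 1.0 and a 5x lr
drop for the final third of the epochs. Per-sample (t, noise) draws are
keyed on the sample index and fixed across epochs, which makes the
epoch-mean loss a deterministic function of the weights (asserted via the
lr = 0 test).

Restoration of a frame: compute the refined mask at t = 0,
forward-diffuse frame and mask to step D (stored trajectories, shared
schedule, independent noise), then iterate the network from t = D down to
1 conditioning on the stored soft mask. The default stepping re-anchors
each estimate to the carried diffusion state: from the step estimate an
implied x_0 and noise direction are extracted and recombined at the
t - 1 noise level. Feeding the raw estimate straight back in (available
as `stepping="direct"`) lets per-step regression biases compound over the
chain — measured at desk scale this costs over 15 dB — whereas anchoring
keeps every input on the training distribution and bounds the
accumulated bias; this is the deterministic-sampler construction
standard in diffusion restoration.

### Ablation semantics

Two ablation notions are exposed. `run_ablation` and the asserted
direction property train architecture variants (pressure stream only;
+ mask stream and cross-attention; + the atrous pyramid) and compare
median restoration error on held-out frames over a shared seed set — the
frame-wise split, because restoration is a frame-level task (the
activity-disjoint split belongs to Stage 2, and on it the two variants
are statistically tied at desk scale). A second notion holds the full
architecture fixed and zeroes the mask *input*
(`train_stage1(..., zero_mask=True)`), isolating the information the
refined mask contributes; at desk scale that information alone is
slightly harmful under activity shift — the refined mask is a
deterministic function of the input frame, so its value at full scale is
an inductive-bias and optimisation aid rather than extra information.
Stabilising the fusion mattered more than either comparison: the
cross-attention output projection is initialised near zero, so the fused
model starts as the pure pressure-stream function and grows its use of
the mask by need.

## Stage 2: pose regression

The (restored) frame is normalised by the sensor ceiling, cut into
non-overlapping patches, linearly embedded with learned positional
embeddings, and passed through pre-norm transformer blocks
(LayerNorm -> multi-head self-attention -> residual, LayerNorm -> MLP ->
residual). The token grid is re-spatialised and upsampled by
deconvolution blocks (2 x 2 stride-2 transposed convolution, batch
normalisation, ReLU), flattened row-major, and mapped by one affine layer
to J x 3 = 36 coordinates. Joint coordinates are standardised (per-joint
mean, global standard deviation of the training poses); the statistics
live on the model as buffers so a reloaded checkpoint predicts
identically. Training is MSE/Adam on the standardised coordinates;
evaluation reports MPJPE and per-axis AKLEB in millimetres on the
activity-disjoint validation split, against the constant mean-pose
predictor as the floor baseline.

The printed description of the keypoint head calls its output
"12-dimensional"; twelve 3-D keypoints require 36 numbers, and the
per-joint metrics are only defined on [J x 3] arrays, so the head emits
J x 3 with J configurable.

## Metrics

PSNR uses the physical ceiling (15 kPa) as the peak value, not 255 — the
frames are measurements, not 8-bit images. SSIM is computed with
Gaussian-weighted 11 x 11 windows (sigma 1.5, k1 = 0.01, k2 = 0.03),
border-cropped before averaging; it matches the reference implementation
in scikit-image to 1e-4 in the tests. The perceptual distance follows
the LPIPS recipe — per-layer, per-position channel-unit-normalised
feature differences, squared, averaged over positions, weighted-summed
over layers — but uses a fixed-seed random two-layer convolutional
extractor, so it requires no pretrained download; its values are
comparable only to themselves. MPJPE defaults to the conventional
1/(N·J) normalisation (a literal sum-over-joints switch exists); AKLEB is
the per-axis mean absolute coordinate error.

## Problem sizes

The test-suite presets were sized for a single laptop-class CPU core:
32 x 20-pixel frames for training experiments (about 200 scenes, D = 10,
five epochs), the 64 x 40 raster for mask-behaviour and ablation
experiments, U-Nets of depth 2 with 8–16 base channels, and a pose
network with d_model 32 and one encoder block. At these sizes Stage-1
training takes tens of seconds and the full seeded pipeline a few
minutes. The numbers produced at this scale demonstrate directions and
mechanics (restoration gain, baseline-beating pose error,
information-ablation ordering), not the magnitudes reachable with a
full-size model on real data.

## Known limitations

- The autodiff engine is float64 and single-threaded; it is sized for the
  desk-scale networks, not for GPU-scale replication.
- The renderer's Gaussian footprints and equal load sharing are crude
  body mechanics; activity-disjoint generalisation in Stage 2 is limited
  by how much the held-out activities' contact patterns resemble the
  training ones.
- Diffusion restoration at D steps costs D network evaluations per frame.
- The LPIPS-style metric with the built-in extractor does not reproduce
  published LPIPS magnitudes; supply a pretrained extractor for
  comparability.
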