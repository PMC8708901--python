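# Methods

## Problem setting

A top-view RGB-D camera observes one pot per 66×66 crop at one frame per
15 minutes.  Colour frames exist only during the 16 h photoperiod (64
frames); the active-IR depth channel records through the 8 h night (32
frames) as well.  Depth is the camera-to-surface distance in millimetres,
so plant growth *decreases* depth.  Each frame is annotated with one of
four ordered growth stages — soil (`SOIL`), first appearance of the
cotyledon (`FA`), opening of the cotyledons (`OC`), appearance of the
first leaf (`FL`) — and stage labels are monotone non-decreasing in time.
Two tasks are addressed: per-frame stage classification by RGB-D fusion,
and depth-only localisation of a stage switch that happens during a
night.

## Synthetic data generator

Real bean time-lapse data of this kind is not publicly deposited, so the
package ships a simulator whose defaults reproduce the dataset structure
the pipeline targets: 616 frames per sequence (424 day + 192 night,
arranged in 64-day/32-night blocks with leftovers appended), six named
varieties, and a 60/6/6 train/validation/test split (10/1/1 sequences per
variety), which yields 36,960 training images and 3,696 in each of the
other splits.

Per sequence the generator renders, on a fixed random soil texture:

- a small raised bud during `FA` (+3 mm canopy, ~5 px radius),
- an abrupt canopy rise at `OC`: +10 mm (default) over an ellipse of
  ~14 px radius, i.e. more than 10 % of the pixels change by at least the
  configured step between two consecutive frames — this is the signal the
  night detector exploits,
- an extra lobe and slight rise at `FL`.

Canopy *depth* is constant within a stage (in the noise-free setting the
depth field is exactly piecewise-constant per stage), while the *RGB*
appearance changes gradually inside every stage (the blob widens and
greens as the stage progresses).  Per-variety presets scale cotyledon
size, ellipse aspect and hue to emulate cultivar heterogeneity.

Noise model: i.i.d. Gaussian per-pixel depth noise (default σ = 2 mm,
a plausible figure for a low-cost stereo-IR depth camera at ~0.5 m),
i.i.d. per-pixel dropouts (default 2 %) plus an occasional contiguous
dropout blob (10 % of frames) mimicking specular/absorbing patches, and
no RGB at night.  Stage onsets are drawn uniformly within ±30 % of mean
durations (defaults 180/140/140 frames), so switches fall in days or
nights by chance; `generate_switch_episode` places a chosen transition at
a known offset inside a night for controlled experiments.

What the simulator does **not** emulate: photorealistic leaf texture and
shading, plants growing out of the crop, inter-pot occlusion, correlated
(non-white) depth noise, and illumination drift.  Passing tests therefore
demonstrate the pipeline's mechanics and its behaviour under the stated
signal/noise geometry, not field performance on real imagery.

The duration arithmetic of a one-week, 96-frames-per-day acquisition
(672 frames) differs from the 616-frame sequence total the package
reproduces; day/night frame counts are therefore explicit configuration,
with 424/192 as the default preset.

## Preprocessing

- **Inpainting.**  Missing depth pixels are filled by deterministic
  boundary propagation: pixels adjacent to valid ones take the mean of
  their valid 8-neighbours, and the front sweeps inward until the mask is
  empty.  Valid pixels are bit-identical before and after, and filled
  values are bounded by the valid neighbourhood's min/max (a mean of
  means cannot escape the hull).  An all-missing frame is an error.
- **Scaling.**  RGB is divided by 255.  Depth is mapped affinely to
  [0, 1] by a *dataset-level* min/max fitted on the training split only
  and applied unchanged to validation/test — per-frame normalisation
  would leak the stage (the canopy height) into the scale.  The mapping
  is recorded for inversion; a degenerate range maps to 0.5 with a
  warning.
- **Windowing.**  Classifiers consume day frames only (annotation is
  RGB-based, hence day-only).  Temporal models use 4-frame windows (1 h)
  labelled by the last frame, matching causal monitoring.  By default the
  day frames form one stream (`(n_day − 4) + 1` windows per sequence);
  `span_nights=False` restricts windows to runs of consecutive frames.
  Stride 1 for training and evaluation by default.
- **Augmentation.**  Deterministic doubling of the training set with a
  horizontal flip applied identically to RGB and depth and to every frame
  of a window; no stochastic per-batch augmentation.

## Classifiers

All variants end in a 4-way softmax and are trained from scratch — the
4-channel input rules out RGB-pretrained weights.

- **CNN** (memoryless, single frame): four 3×3 convolutions with 64, 128,
  256, 256 filters, each followed by ReLU and 2×2 max-pooling
  (66→33→16→8→4), then a 512-unit dense layer with ReLU and dropout
  p = 0.5.  Image fusion feeds the 4-channel stack to one such network;
  feature fusion runs one conv stack per modality and concatenates the
  flattened conv features before the shared 512-unit dense layer.
- **TD-CNN-GRU**: the same CNN applied time-distributed (shared weights)
  to each of 4 consecutive frames, followed by a single GRU layer (64
  units — width is a package choice, exposed in the spec) and the head.
  Feature fusion runs per-modality CNN+GRU streams and concatenates the
  final hidden states after the temporal block.
- **Transformer**: each whole 66×66 frame is one token (the crop *is* the
  meaningful unit, so no patching); tokens are linearly projected, given
  learned positional embeddings, and passed through a pre-norm encoder
  stack with mean-pooled output.  The named `paper` preset keeps the
  32-layer depth with batch size 64; heads (4), width (128) and the
  positional-encoding type are unstated externally and are package
  defaults.  A `desk` preset (2 layers, width 32) keeps CPU runs honest.
  For feature fusion each modality has its own (equal-depth) stack and
  the pooled outputs concatenate.

Depth-only classification (`fusion="none_depth"`) is wired up solely as a
negative control — a depth-alone classifier performs at chance on this
problem, which is why decision-level fusion is not offered.

The networks run on a small reverse-mode autograd engine written on
NumPy (float64, CPU): broadcast arithmetic, batched matmul, 3×3
same-padding convolution as nine shifted contractions, 2×2 max-pooling,
layer norm, softmax attention, dropout, fused softmax cross-entropy.
Every backward pass is validated against central finite differences in
the test suite.  Weight initialisation is Glorot-uniform from an explicit
seeded generator: the same seed reproduces bit-identical models and
training runs on one platform.

## Training protocol

Splits are stratified by variety: every variety contributes sequences to
train, validation and test, and no sequence appears in two splits.
Optimisation uses Adam (lr 10⁻³), cross-entropy, batch size 64, up to 50
epochs with early stopping (patience 10) on validation accuracy and
restoration of the best-validation weights; none of these were externally
fixed, so they are standard defaults exposed in `TrainConfig`.
Experiments repeat over a seed list (default 10 repetitions) and report
mean ± sample (n−1) standard deviation per split, plus the test confusion
matrix summed over repetitions.  Accuracy is overall (micro) accuracy,
trace/total of the 4×4 confusion matrix — for multi-class data the
binary (TP+TN)/(TP+TN+FP+FN) form is implemented one-vs-rest and
macro-averaged as a secondary metric.  Accuracies are per frame (CNN) or
per window (temporal models); per-sequence aggregation is not used.

Desk-scale experiment sizes used by the test suite: two varieties × one
sequence per split, 128 day frames per sequence, window stride 2,
12 epochs, 3 repetitions, and reduced-width model presets.  These sizes
are the package's own choice of a laptop-scale experiment; the full-scale
presets remain available unchanged.

## Night-event detection

Inputs are depth frames of the last day at stage A (`Sa`), the night
(`Snight`) and the first day at stage B (`Sb`), all inpainted.  With
per-frame spatial means `DN(k)` and stage levels `MDA`/`MDB` (temporal
means of the day series), the detector marks night frame k when
`|DN(k) − MDA| > |DN(k) − MDB|` — strictly closer to the next stage —
and returns the first index `Idx` opening a run of 4 consecutive marks,
reported as `Pt = len(Sa) + Idx` (0-based into `Sa‖Snight`, so
`Pt ∈ [len(Sa), len(Sa)+len(Snight)−4]` when detected).

Numerical choices: a tie (`exactly halfway`) counts as *not yet* closer to
B (conservative); the first qualifying run wins; the run length (4 frames
= 1 h) is the "persistently closer" horizon and is a parameter; absence
of any such run returns a no-detection outcome carrying the full trace.
Note that comparing the *signed* differences `DN − MDA` vs `DN − MDB`
instead of absolute closeness is degenerate — their difference is the
constant `MDB − MDA`, independent of the night frame — so closeness must
use absolute values; `literal_sign_bin` exposes the degenerate variant
only to document this, and a test pins the behaviour.

Ground truth for real nights cannot be annotated from RGB, so validation
re-casts *daylight* switches as pseudo-night episodes: the depth frames
of a 32-frame window containing an annotated switch play the night, with
up to 64 frames of context on each side as `Sa`/`Sb`, and the detector —
seeing depth only — is scored against the RGB-derived truth.  The report
gives the fraction of events within a 4-frame tolerance and the mean and
standard deviation of the absolute shift, covering both readings of an
"average shift below 4 frames" statement.

At the default signal regime (10 mm step ≥ 5× the 2 mm noise, over ≥10 %
of pixels) the spatial mean over 66² pixels suppresses noise by a factor
~66, so recovery is essentially exact; the acceptance script measures the
within-4-frames rate on 100 simulated episodes, and a Monte-Carlo test
checks that localisation error is non-increasing in step magnitude.

## Known limitations

- The simulator's stage-constant depth makes night detection easier than
  real canopies with continuous growth; the detector's step model is,
  however, exactly the cotyledon-opening geometry it targets.
- One switch per night is assumed (the episode contract); multi-switch
  nights are out of scope.
- Spatial means use the whole frame; crops are single-pot by
  construction, so no pot-centred region is applied.
- Training determinism is platform-level (BLAS reduction order may differ
  across machines); within one platform runs are bit-reproducible.
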