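# Methods

## Problem and model

`echomasa` segments the left ventricle (LV) in echocardiography video. The
clinically annotated frames are end-diastole (ED) and end-systole (ES); the
model consumes an 8-frame clip laid out as 4 frames before the key frame,
the key frame, and 3 frames after, and predicts a binary LV mask for the key
frame only (supervision exists only there). The pipeline has three parts:

1. **Temporal Feature Fusion Module (TFFM).** The clip's T frames are
   concatenated along channels (T·C fused channels). A strided r×r
   convolution folds spatial detail into channels and emits a stack of
   3·r²·D channels read as query / key / value blocks in that order.
   After flattening the compressed spatial grid, each block is partitioned
   along the temporal–channel axis into non-overlapping windows of three
   lengths w₁ < w₂ < w₃; within each window group, standard softmax
   attention `softmax(QKᵀ)V` (a wᵢ×wᵢ matrix per group) mixes temporal–
   channel slots. Each window size has its own learned transposed-conv
   restoration back to (T·C, H, W); the three restorations are summed onto
   an identity skip of the fused clip. A channel-aggregation (CA) stage
   then computes an expanded representation
   `Y = GELU(DWConv3×3(Conv1×1(LN(X))))`, extracts a single-channel
   "universal" feature `GELU(Conv1×1(Y))`, and refines
   `CA(Y) = Y + s ⊙ (Y − X_u)` with a learnable per-channel gain `s`
   (initialized at 0, so the refinement starts disabled), followed by a 1×1
   projection and a residual to the TCSA output.

2. **Vision RetNet encoder.** Four stages of retention-style attention with
   an explicit spatial prior: attention weights are multiplied by
   `γ^distance`, where distance is the Manhattan distance between token
   grid coordinates. Stage layout: a stride-4 stem (two stride-2 3×3
   convolutions; a single-conv stride-2 stem is available behind
   `stem_double=False`), then stride-2 3×3 downsampling before stages 2–4,
   giving pyramid strides {4, 8, 16, 32}. Each layer applies conditional
   positional encoding (residual depth-wise 3×3), pre-norm Manhattan
   self-attention with a parallel local-context-enhancement branch
   (depth-wise 5×5 on the value path), and a pre-norm 2-layer GELU FFN;
   every sub-block is residual, so a zero-initialized layer is the
   identity. Stages 1–3 use the *decomposed* attention (two 1D attentions,
   one per grid axis, sharing Q and K; the N×N decay matrix is never
   built); stage 4 uses the full 2D form on the coarsest grid.

3. **FPN decoder.** The four pyramid levels are projected to a common width
   by 1×1 convolutions, bilinearly upsampled to the stride-4 resolution,
   and summed. The head is LN → 3×3 conv → LN → GELU → 1×1 conv (its bias
   initialized at a positive prior, see Training), upsampled bilinearly to
   the input resolution.

## Attention conventions

Token fields are (H, W, d); token (x, y) sits at row x, column y, and
row-major flattening is used everywhere. Full MaSA is
`(softmax_rows(QKᵀ) ⊙ D2d) V` with `D2d[n,m] = γ^(|xₙ−xₘ|+|yₙ−yₘ|)`; the
rows are **not** renormalized after the Hadamard mask. The decomposed form
applies the height-axis attention first (per column, decay `γ^|Δx|`), then
the width-axis attention (per row, decay `γ^|Δy|`); both reuse the same Q
and K. On 1×W or H×1 grids the unused factor is the identity and the two
forms agree exactly — this, plus entry-wise brute-force evaluation, pins
the transposition contract in the tests rather than notation.

Multi-head attention uses one decay rate per head,
`γ_h = 1 − 2^(−5−h)` (the retention lineage's schedule; the source work
names the mechanism but no values), configurable per stage.

The reference implementations in `echomasa.attention` compute in float64
and serve as numerical oracles (agreement with brute force < 1e-6 on all
grids up to 6×6); the network layers compute in float32.

## Complexity accounting

`op_counts_masa_*` count every scalar operation: multiply–adds of the
matrix products, the Hadamard mask, and the softmax interior (per row of
length L: L subtractions, L exponentials, L−1 additions, L divisions).
Counting the softmax matters: on matmul MACs alone the two forms tie on a
2×2 grid, while the complete budget is strictly smaller for the decomposed
form on every square grid with side ≥ 2. Asymptotically the decomposed
form costs O(N·(H+W)·d) — on square grids O(N^1.5·d), i.e. ~2.8× per
exact doubling of N — versus O(N²·d) (4× per doubling) for the full form.
The empirical benchmark (`doubling_time_ratio`) times the float32 layer
implementations over grids 16×16 → 32×16 → 32×32 → 64×32 → 64×64 (N = 256
to 4096, d = 32, best-of-k timing, decay matrices cached as in a model) and
observes ~2.1–2.3 per doubling for the decomposed form (partially
overhead-bound at these sizes) versus ~4.5–5 for the full form.

## Training

The loss is the mean absolute error between the predicted mask map and the
binary key-frame mask, optimized with AdamW and a step learning-rate decay.
Full-scale defaults follow the protocol the model family is trained with:
lr 1e-4, batch 8, 50 epochs, decay ×0.1 at epochs 30 and 45, and per-clip
augmentation (random horizontal flip, ±20° rotation, 0.9–1.1 scale,
±0.0625 shift, 0.8–1.2 brightness/contrast; one geometric draw applied
identically to all frames and to the mask with nearest-neighbour
resampling, photometric jitter on frames only).

Two head parameterizations exist (`ModelConfig.head`):

* `"sigmoid"` — the map is `sigmoid(logits)`; masks threshold the
  probability at 0.5. This is the default for the full-size configuration.
* `"linear"` — the head output itself is the mask map (clipped to [0, 1]
  at inference), trained by the same MAE criterion and thresholded at 0.5.

The linear head exists because MAE on sigmoid probabilities has gradients
proportional to σ′(logit): under heavy class imbalance the background
drives all logits into float32 saturation and learning freezes — at small
data scales and from random initialization the sigmoid variant reliably
collapses to the empty mask, which we verified while a cross-entropy
control converges. L1 regression of the map keeps a constant-magnitude
gradient everywhere. Even so, L1 regression of a ~10%-foreground mask has
the all-background map as its pixelwise-median optimum, and a cold-started
network can stall there. Four stabilizers address this regime: LayerNorm
on the fused FPN map and before the head's GELU (prevents a saturated,
frozen head), a positive prior initialization of the head's output bias
(0.2, so the background's initial descent keeps gradients flowing through
the features from the first step), the TCSA identity skip described above
(without it a randomly initialized fusion module can erase the key frame's
intensity signal), and an AdamW second-moment constant of 0.99 (shorter
variance memory adapts faster through the takeoff where the loss landscape
changes abruptly).

## Synthetic phantom

The generator emulates the phenomenology that makes LV segmentation hard,
not ultrasound physics: a dark elliptical lumen in a brighter myocardial
rim over a mid-gray background, multiplicative speckle, Gaussian blur, a
fan-shaped scan sector, and occasional out-of-view truncation (the sector
apex is shifted sideways so a ventricle edge leaves the field of view).
Speckle is unit-mean gamma-distributed multiplicative noise (the
squared-magnitude Rayleigh family); its standard deviation is the
configured strength (default 0.5, with σ = 1 corresponding to fully
developed speckle before blurring). The ellipse axes scale with
`s(t) = 1 − (1 − √f)(1 − cos 2πt)/2` over cycle phase t, so the area is
maximal at ED (t = 0), minimal at ES (t = 0.5), and the ES/ED area ratio
equals the systolic area fraction f (default 0.5, a normal-range area
change). Default clips render one full cycle in 16 frames with ED at index
4 and ES at index 12, so both key frames admit the 4-before/3-after window
and always survive dataset cleaning. Masks are the exact ellipse-interior
pixels clipped to the sector.

What the phantom does **not** model: papillary muscles and trabeculation,
anisotropic point-spread functions, attenuation/shadowing, probe motion,
and inter-view anatomy differences. Passing tests on phantoms therefore
demonstrates that the architecture, losses, metrics and data plumbing are
correct and that the model can learn this class of shapes from video — not
that the reported clinical-data accuracies are reproduced.

## Data dialects

* **EchoNet-style**: one grayscale video per file plus `FileList.csv`
  (FileName/NumberOfFrames/Split) and `VolumeTracings.csv`
  (FileName/X1/Y1/X2/Y2/Frame; X = column, Y = row), matching the
  EchoNet-Dynamic table schema. Videos are stored as multi-page TIFF — a
  lossless, dependency-light container. Key-frame types are assigned by
  traced area (the larger of a video's two traced frames is ED).
  Tracings rasterize by walking the paired left points top-to-bottom and
  right points back, filling with the pixel-center even-odd rule plus the
  boundary pixels; an axis-aligned k×m rectangle trace fills exactly k·m
  pixels, and convex masks round-trip with dice 1.0.
* **CAMUS-style**: per-patient MetaImage volumes per view
  (`<pid>_<view>_half_sequence.mhd`, `<pid>_<view>_{ED,ES}_gt.mhd`) with
  ED/ES indices in `Info_<view>.cfg`; only the endocardium label (default
  1) is kept as the LV.

Dataset cleaning keeps exactly the records whose every key frame admits
the full 8-frame window; it is idempotent and order-preserving.

## Metrics

Dice is `2|A∩B|/(|A|+|B|)`; two empty masks score 1.0, empty-vs-non-empty
scores 0.0. Hausdorff distances are computed between inner boundaries
(mask pixels with an 8-neighbour outside), in pixels. HD95 takes the 95th
percentile of each directed distance distribution and then the max of the
two directions, so HD95 ≤ HD always; an empty mask yields the image
diagonal as a sentinel. Reports aggregate by arithmetic mean over key
frames, ED and ES pooled, with a per-type breakdown available.

## Problem sizes for the bundled sanity runs

The learning checks run a reduced configuration — widths (16, 32, 64, 128),
depths (1, 1, 2, 1), heads (2, 2, 4, 8), TFFM r = 2, D = 8, windows
(2, 4, 8), linear head, 64×64 single-channel phantoms — chosen as the
smallest model that still exercises every architectural component:

* **Single-clip overfit**: ≤ 500 steps, lr 1e-3, batch 1, no augmentation,
  decay at steps 250/400; reaches key-frame DSC ≥ 0.90 (typically within
  100–350 steps).
* **64-clip corpus**: 70/15/15 split, 10 epochs at batch 1 (880 steps),
  lr 1e-3, no augmentation, decay at epoch 8; held-out DSC ≈ 0.93 and
  HD95 ≈ 1.3–1.7 px across seeds. Batch 1 is deliberate: within a fixed
  10-epoch budget it provides 8× more optimizer steps than the full-scale
  batch of 8, which the small corpus needs to escape the all-background
  L1 optimum. Augmentation is off in these short runs for the same
  reason; the full-scale defaults keep it on.

## Known limitations

* The full-size model (depths 3/4/18/4, widths 64–512) is buildable and
  its parameter count reportable, but training it is out of desk scale;
  all learning evidence comes from the reduced configuration on phantoms.
* The sigmoid-head MAE path matches the literal training recipe but is not
  trainable from random initialization at small scale (see above); use the
  linear head for small experiments.
* The decomposed attention is sub-quadratic but not strictly linear in N
  on square grids (O(N^1.5·d)); the benchmark documents the measured
  growth honestly.
* Augmentation commutes with rasterization only to boundary-pixel
  tolerance; masks are resampled nearest-neighbour.
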