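# Methods

This note documents the models, numerical choices, and known limitations of
the ofpcanet pipeline: dense optical flow with a trajectory-subspace
regularizer, sliding-window flow stacking, two-layer PCANet+ feature
learning, and linear-SVM classification under leave-one-subject-out (LOSO)
cross-validation.

## Problem setting

The pipeline classifies short grayscale video clips of pre-cropped faces by
the subtle, localized motion they contain (micro-expressions: involuntary
facial movements of roughly 1/25–1/2 s duration and sub-pixel to few-pixel
amplitude). Because motion — not appearance — carries the class signal, the
raw frames are first converted into dense optical-flow fields against the
clip's first frame; the flow sequence is then stacked into multi-channel
images from which convolutional features are learned analytically.

## Optical flow with a trajectory subspace

For a clip `I ∈ R^{N×M×L}`, frame 1 is the reference and displacement
fields `(u_t, v_t)` are estimated for each of the L−1 remaining frames.
The solver minimizes a discretized energy with three terms:

- **brightness constancy** (weight `alpha`, default 10): a robust
  Charbonnier penalty `√(r² + ε_b²)`, `ε_b = 10⁻³` intensity units, on the
  residual between each warped frame and the reference;
- **trajectory subspace** (weight `beta`, default 1): the squared distance
  between each pixel's displacement trajectory `(u(t), v(t))`, t = 1..L−1,
  and its least-squares projection onto the span of R basis trajectories.
  The default basis is the first `R = min(6, L−1)` orthonormal discrete
  cosine trajectories — smooth, orthogonal, and frequency-ordered, the
  standard choice for trajectory subspaces; a custom basis matrix may be
  supplied (it is orthonormalized by QR). The projection is applied to the
  u and v components separately, which is equivalent to a 2R-dimensional
  basis of R² trajectories;
- **total variation** (weight 1): coupled Charbonnier-TV
  `√(|∇u|² + |∇v|² + ε_tv²)` on each field, forward differences.

Minimization is block-coordinate and fully deterministic (no randomness,
zero initialization):

1. **Sequential per-frame pass.** Each frame is solved coarse-to-fine over
   an image pyramid (3 levels, scale 0.5 by default) with iterative
   warping: linearize the brightness term at the current flow (Taylor
   expansion under the small-motion assumption), reweight the robust terms
   (IRLS / lagged diffusivity), and run a few vectorized Jacobi sweeps on
   the resulting 2×2-coupled linear system per pixel. Because flow against
   a fixed reference grows roughly linearly with frame index, frame t's
   coarsest level is warm-started from frame t−1's solution, so only the
   incremental per-frame motion has to be recovered from scratch. This is
   what keeps cumulative displacements of many pixels tractable while each
   per-frame increment stays within the pyramid's capture range.
2. **Joint trajectory refinement.** At the finest level all frames are
   refined together, alternating the linearized update with the
   closed-form projection of trajectories onto the basis span. A
   backtracking step guard (try the full update, then damped fractions;
   keep the previous iterate if nothing descends) makes the tracked energy
   non-increasing over outer iterations by construction. The energy values
   are recorded in `FlowSequence.energy_history`.

Numerical details that matter:

- `ε_tv = 0.05` px. The lagged-diffusivity weight is `1/(2√(|∇w|² + ε_tv²))`
  and diverges as the flow becomes smooth; with too small an epsilon the
  TV term's mobility cap dwarfs the data term and the solver stalls near
  zero. 0.05 px balances the two caps while keeping the TV term within a
  few percent of exact at flow gradients above ~0.2 px.
- "50 iterations per level" means 50 outer linearizations, each with 3
  Jacobi sweeps.
- Warping uses bilinear interpolation with out-of-bounds samples clamped
  to the border; image gradients are central differences of the warped
  frame; flow upsampling between levels is bilinear with value rescaling.
- The `pairwise` backend sets `beta = 0` and skips the projection, solving
  each frame independently; it is the degenerate limit of the trajectory
  backend and the two agree to well below 10⁻³ px when `beta → 0`.

On 64×64 synthetic textures, global translations up to 3 px/frame are
recovered with mean endpoint error around 0.01–0.05 px, and identical
frames yield exactly zero flow.

## Sliding-window stacking

The flow sequence (L−1 fields) is cut into windows of T consecutive
frames at step `s = max(1, ⌊(T−1)/2⌋)` by default; each window yields one
N×M×2T tensor — the T u-fields followed by the T v-fields. The window
count is `⌊((L−1)−T)/s⌋ + 1`: only complete windows inside the flow
sequence are produced, and trailing frames not covered by a window are
dropped. (A count formula written against the clip length L instead of
the flow length L−1 would index one frame past the sequence for some L;
this implementation guarantees every window is valid.) With T = 1, s = 1
the operation is the identity: one 2-channel tensor per flow frame.

## PCANet+ feature learning

Each layer's D filters are the top eigenvectors of the scatter matrix
`P Pᵀ` of mean-centered k×k×C patches (one patch per pixel, zero padding
`(k−1)/2` for same-size output), i.e. the orthonormal basis minimizing
patch reconstruction error. Properties and choices:

- **Streaming scatter.** `P Pᵀ` is accumulated one image at a time, so peak
  memory depends on the patch dimension (k²C), not the batch size, and
  training is order-invariant. An optional `learn_step` subsamples patch
  positions during accumulation only (adjacent patches are highly
  redundant); inference always uses every position.
- **Sign convention.** Each eigenvector is flipped so its
  largest-magnitude component is positive (ties: first index), making
  filters reproducible across eigensolvers. Tied eigenvalues keep the
  solver's descending order; the spanning filters of a tied eigenspace are
  not unique and this is documented rather than hidden.
- **Correlation, not flipped convolution**, applied to the raw
  (zero-padded) image; patch-mean centering applies only during learning.
- **Mean pooling** (default 3×3, stride 1, reflect borders) after layer 1
  provides the nonlinearity between layers and feeds layer 2.
- **Encoding.** Pooled response maps are split into chunks of
  `F_λ = 8` maps; each chunk is hashed per pixel by the Heaviside step
  (`H(x) = 1` iff x > 0) with binary weights `2^{f−1}` into labels in
  `[0, 255]`; each label map is partitioned into `B` non-overlapping
  blocks (default 2×2, remainder pixels to the last row/column) and
  histogrammed over the 256 labels. Both layers are encoded and
  concatenated: the feature length is `Σ_l B_l (D_l / F_λ) 2^{F_λ}`
  exactly, and each hash map contributes exactly N·M counts — conservation
  laws the tests verify against brute-force counting.
- The block count/geometry is not determined by the published
  architecture; 2×2 is the package default and configurable.

The LOSO protocol is honored during learning: filters are trained per fold
from the training subjects' tensors only.

## Classification and metrics

Per-tensor features of a clip are aggregated by element-wise mean (sum
optional), standardized per dimension with training-fold statistics, and
classified by a linear one-vs-rest SVM (C = 1, no inner tuning). Folds
leave out one subject each, in first-appearance order; predictions are
pooled into a single confusion matrix before computing accuracy, per-class
precision/recall (0/0 → 0 with a warning), macro-F1, and macro-recall.
Macro-recall averages `TP_i/(TP_i+FN_i)`; the precision-averaged variant is
reported alongside as `macro_precision`.

## Synthetic data: what it emulates and what it does not

The generator fabricates the structure the pipeline assumes: per-subject
random textures (smoothed noise or Gaussian blobs) standing in for facial
appearance, warped by class-specific smooth Gaussian-bump displacement
fields (distinct locations and directions, mimicking sparse facial action
units) growing linearly in time, plus post-warp i.i.d. intensity noise that
mildly violates brightness constancy. Defaults are the study conditions
used throughout the tests: 6 subjects × 3 classes × 3 clips, 64×64 frames,
12 frames per clip, 2 px/frame peak amplitude, noise σ = 0.01, seed 0.
Ground-truth fields are written as `.flo` files. Generation is
byte-deterministic under a fixed seed.

It does **not** emulate: facial appearance or identity confounds,
camera/illumination variation, head pose, nonlinear temporal envelopes
(onset–apex–offset), occlusion, or the label imbalance of real corpora.

**Consequently, what passing tests show is bounded.** Under these
conditions the full pipeline separates the classes perfectly (pooled LOSO
accuracy 1.0) — with and without temporal stacking. Each class is
identifiable from any single clean flow field, so the T = 3 vs T = 1
comparison saturates at the ceiling and the benefit of stacking observed
on real micro-expression data (where per-frame flow is noisy and weak) is
not measurable here. The sweep harness reports both settings; a strict
improvement from stacking should not be expected on this synthetic task,
and its absence says nothing about real data.

## Problem sizes

Tests and the acceptance script run at deliberately small scale chosen as
representative rather than exhaustive: 64×64 synthetic clips for flow and
end-to-end checks; one 170×139 clip with subsampled patch learning
(`learn_step = 8`) for the published-architecture check (bank shapes are
invariant to patch subsampling); random matrices of a few hundred columns
for the eigen-oracle comparisons.

## Known limitations

- The flow solver targets the sub-pixel-to-few-pixel-per-frame regime;
  localized displacements accumulating beyond ~10 px against the reference
  frame are increasingly underestimated (TV smoothing and the warm-start
  chain both favor smooth, moderate motion).
- Backward warping of a fixed bump field is only an approximation of
  coherent object motion for large t; the generator's ground truth is
  exact for the warp it applies, not for a physically advected field.
- Linear-SVM one-vs-rest with C = 1 is deliberately untuned; on harder
  data an inner model-selection loop would be warranted.
- Hash labels depend on response signs only; any global sign flip of a
  filter (prevented by the sign convention) would permute histogram bins.
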