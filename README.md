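# ofpcanet

Spatiotemporal feature learning for subtle facial-motion (micro-expression)
video classification: **temporally consistent dense optical flow → sliding-
window flow stacking → two-layer PCANet+ → linear SVM**, evaluated under
the person-independent leave-one-subject-out (LOSO) protocol.

Micro-expressions are involuntary facial movements lasting a fraction of a
second with sub-pixel to few-pixel amplitude. Annotated corpora are tiny
(a few hundred clips), which rules out large backprop-trained networks;
this package instead learns its convolution filters *analytically* — each
layer's filters are the principal eigenvectors of the local patch scatter —
so the whole feature extractor is deterministic, data-efficient, and
trainable in seconds. Motion, not appearance, carries the class signal, so
the network input is not raw frames but dense optical flow.

## Method

For a clip `I ∈ R^{N×M×L}` (first frame = reference):

1. **Flow.** For every frame t ∈ {2..L}, displacement fields
   `(u_t, v_t)` are estimated by minimizing

   `E = α Σ_t ∬ |I(x+u_t, y+v_t, t) − I(x, y, 1)|
      + β Σ_t ∬ ‖(u_t, v_t) − Π_Q(u, v)(t)‖²
      + Σ_t ∬ ‖∇(u_t, v_t)‖`

   where `Π_Q` projects each pixel's displacement trajectory onto the span
   of R basis trajectories (discrete cosine curves by default) — a subspace
   model that keeps the flow temporally consistent across the clip. The
   solver is coarse-to-fine with iterative warping, IRLS-weighted Jacobi
   updates, a sequential per-frame warm start, and a backtracking guard
   that makes the tracked energy non-increasing. A `pairwise` backend
   (β = 0, frames independent) is available for testing.
2. **Stacking.** A sliding window of T flow frames (step
   `s = ⌊(T−1)/2⌋`, at least 1) yields N×M×2T tensors: T u-fields then
   T v-fields.
3. **PCANet+.** Layer 1 learns D₁ filters of size k₁×k₁×2T as the top
   eigenvectors of the mean-centered patch scatter; responses are 3×3
   mean-pooled (the inter-layer nonlinearity) and feed layer 2 (D₂ filters,
   k₂×k₂×D₁). Each layer's maps are divided into chunks of F_λ = 8, hashed
   per pixel by the Heaviside step with binary weights into labels in
   [0, 2^F_λ −1], and histogrammed over B non-overlapping blocks. Both
   layers' histograms concatenate into a feature of length
   `Σ_l B_l (D_l/F_λ) 2^{F_λ}`.
4. **Classification.** Per-clip mean-aggregated features, standardized with
   training-fold statistics, linear one-vs-rest SVM (C = 1). One LOSO fold
   per subject; the filter bank is retrained per fold from training
   subjects only; per-fold predictions pool into one confusion matrix from
   which accuracy, macro-F1 and macro-recall are computed.

Shipped presets encode the published best architectures:
`smic-best` (T=5; 170×139×10 input; (7×7×10)×32 then (9×9×32)×16) and
`casme2-best` ((7×7×10)×16 then (7×7×16)×32), plus `synthetic-small` for
the bundled synthetic benchmark.

Real micro-expression corpora (SMIC, CASME2) are license-restricted and
not required: `ofpcanet.synthetic_data` generates deterministic labeled
datasets — per-subject textures warped by class-specific localized
displacement fields with ground-truth `.flo` flow — on which every stage
and the full LOSO protocol are testable.

## Worked example

Generate a small synthetic dataset (4 subjects × 3 motion classes × 3
clips of 64×64×8 frames) and evaluate it end to end:

```bash
ofpcanet synth --spec spec.yaml --out data
# {"clips": 12, "subjects": 4, "classes": ["raise", "depress", "spread"], "out": "data"}

ofpcanet evaluate --manifest data/manifest.csv --config cfg.yaml
```

where `spec.yaml` sets `n_subjects: 4, clips_per_subject: 3,
frame_size: [64, 64], clip_length: 8, seed: 3` and `cfg.yaml` is the
`synthetic-small` preset. Output (abridged; ~20 s on one CPU):

```json
{
  "metrics": {
    "accuracy": 1.0,
    "macro_f1": 1.0,
    "macro_recall": 1.0
  },
  "confusion_matrix": [[4, 0, 0], [0, 4, 0], [0, 0, 4]],
  "class_names": ["raise", "depress", "spread"]
}
```

All 12 clips are classified correctly across the 4 LOSO folds: each row of
the confusion matrix is one true class ("raise" = upper-region upward
drift, "depress" = lower-region downward drift, "spread" = radial
dilation), each column a predicted class, and all mass sits on the
diagonal. On this clean synthetic task the localized motion patterns are
fully separable; see `docs/methods.md` for what that does and does not
imply about real data.

Other subcommands: `ofpcanet flow` (cache per-frame Middlebury `.flo`
fields), `train-bank` / `extract` (reusable filter banks and features),
`sweep` (re-run a grid of config overrides, e.g. the stacking window
T ∈ {1,3,5,7} or filter-size/count combinations, one metrics row each).
The same functionality is available as a library
(`ofpcanet.run_pipeline`, `ofpcanet.run_sweep`).

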