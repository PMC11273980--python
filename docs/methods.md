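# Methods

## Scope and design

`tumornet` reconstructs a published-style compact CNN for four-class brain-MRI
classification as a verifiable software artifact. Its contract has two
halves: (i) the architecture and its exact parameter accounting, checkable in
seconds with no data; and (ii) the training/evaluation protocol, checkable at
desk scale on synthetic images. The package deliberately does not attempt to
reproduce headline accuracies on the real Kaggle MRI corpus — that requires
the external download and many GPU-hours — but the harness accepts that run
verbatim (224×224 inputs, 50 epochs, batch 8, five folds).

## Architecture reconstruction

The block stack is resolved to widths **16, 32, 64, 128, 128, 256**. The
prose description of the filter progression lists five widths; the printed
parameter totals, however, are only consistent with one additional width-128
block whose shortcut is the identity (no projection). Under the counting
convention below the blocks contribute

    976 + 6,624 + 25,536 + 100,224 + 165,120 + 397,056 = 695,536

and the head (dense 256→512 plus classifier 512→4) contributes
131,584 + 2,052 = 133,636, giving 829,172; the hybrid attention module at
256 channels adds 99,516, giving 928,688. Every alternative reading of the
block sequence misses these totals by ≥100,000, so the reconstruction is
overdetermined. Pool placement (after blocks 1–4 and 6) does not affect the
count; it is chosen so that a 224×224 input yields a 7×7 final map, and it
is configurable.

**Counting convention.** Convolutions and dense layers carry biases (biases
before BN are mathematically inert — BN subtracts the batch mean — but they
are parameters of the stated layer shapes and are required to reach the
printed totals). Each BN layer counts four numbers per channel: learnable
scale and shift plus non-learnable running mean and variance. This is the
convention under which the closed forms

    conv block:  f·(10·c_in + f + 15)   (projection)   10·f·(f+1)   (identity)
    attention:   1.5·C² + 4.5·C + 60    (even C, ratio 2)

hold, and both are tested against tensor-by-tensor enumeration of
instantiated modules.

**Input channels.** Inputs are 3-channel; grayscale images are replicated.
The first block's 976 parameters pin c_in = 3.

**Attention placement.** Exactly one hybrid attention module is instantiated,
on the 256-channel map after the final pool: the difference of the two
printed totals equals the module's parameter count at C = 256 and at no
other width.

## Numerical engine

No deep-learning framework is assumed: `tumornet.autodiff` is a small
reverse-mode tape over NumPy arrays (im2col convolutions backed by BLAS
matmuls, fused batch-norm and softmax/cross-entropy ops, move-semantics for
gradient buffers). Float32 is the working precision; float64 inputs are
propagated so the test suite can verify every operator against central
finite differences at 1e-5 relative tolerance. Max-pool and global-max
gradients split ties evenly (ties have measure zero on continuous data).
An inference pass inside `no_grad` records no graph.

## Training protocol

- **Split:** shuffled 80/20 with seed 101; the train-size boundary is
  `round(n·0.8)` (7023 → 5618/1405). Unstratified by default, matching the
  protocol's plain shuffle; a stratified variant is available.
- **Folds:** indices are shuffled per run seed and cut into five chunks whose
  sizes differ by at most one; each fold trains a freshly initialized model
  (variance-scaling fan-in normal init) and is evaluated on the same held-out
  test set; reports are averaged arithmetically.
- **Loss:** categorical cross-entropy (natural log; predictions clipped at
  1e-7 in the reference formula) plus λ Σ w² with λ = 10⁻³ applied to
  convolution and dense kernels, not to biases or BN parameters — the stated
  regularization attaches to the convolutions, and penalizing BN statistics
  would be meaningless.
- **Optimizer:** Adam, initial rate 10⁻³, β₁ = 0.9, β₂ = 0.999.
- **Plateau rule:** after each epoch the validation loss is appended to an
  observation window; when the best of the last `patience` (default 5)
  entries fails to improve on the best before them, the rate is multiplied
  by 0.4 (floored at 10⁻⁶) and the window is cleared, so consecutive
  reductions again require `patience` stagnant epochs. No early stopping.
- **Dropout:** rate 0.5 after the 512-unit dense layer, inverted scaling.

### Batch-normalization defaults

Momentum 0.9, epsilon 10⁻³, biased batch variance for normalization.
Momentum is the one place this package departs from framework-default 0.99:
with desk-scale runs (tens of optimizer steps per fold) running statistics
at 0.99 remain close to their initialization, and inference-mode evaluation
then measures noise rather than the trained network. At 0.9 the statistics
converge within a few dozen updates; long runs are insensitive to the
choice, and neither momentum nor epsilon affects parameter counts.

## Synthetic data

The generator emulates only the *statistical shape* of the task: four
balanced classes of single-channel images whose identity is geometric —
centered filled ellipse, centered ring, background texture only, and a
corner blob — with seeded jitter in position/size/orientation, additive
Gaussian pixel noise (default sd 0.05), and values clipped to [0, 1].
Defaults are 100 images per class at 64×64, "easy" contrast. Classes are
written to folders named with the tumor vocabulary so the loader's
lexicographic label order matches the real dataset's. Images are stored as
8-bit PNG to exercise the decode path deterministically.

What passing the synthetic end-to-end test shows: the assembled network,
its gradients, the optimizer, the fold bookkeeping and the metric suite
function correctly and can fit a learnable four-class image problem to ≥90%
averaged test accuracy in ten epochs. What it does not show: anything about
MRI physics, tumor morphology, class imbalance, scanner artifacts, or the
accuracy attainable on real clinical data.

## Numerical and degenerate-input choices

- Softmax is max-shifted; sigmoid uses the two-branch stable form.
- 0/0 metric cells (empty predicted or true class) are defined as 0 and
  flagged on the report rather than raising.
- Summary precision/recall/F1 are macro averages (the published single
  values name no averaging); support-weighted versions are also emitted.
- Per-class accuracies are diagonal-over-row-sum (per-class recall), the
  standard confusion-matrix reading of per-class percentages.
- `reduce_lr_on_plateau` with a history no longer than `patience` returns
  the state unchanged; an empty weight list gives a zero L2 penalty.
- Odd spatial extents are floor-truncated by 2×2 pooling; the architecture
  validator rejects specs whose pool count would underflow the input.

## Problem sizes used in the checks

Parameter accounting runs on the full default architecture (seconds, no
data). Training checks use reduced problems chosen as the smallest sizes
that exercise every code path with stable outcomes: toy two-class sets
(20 images, 16×16) for optimizer contracts, 200 synthetic images at 32×32
with a narrow block stack for cross-validation behavior, and the full
end-to-end check — 400 easy-mode synthetic images at 64×64 through the
complete with-attention architecture, five folds × ten epochs — as the
pipeline's integration test.

## Known limitations

- CPU-only and single-threaded by design; a 50-epoch × 5-fold run on 5,618
  real 224×224 images is supported but slow compared to GPU frameworks.
- The autodiff engine implements exactly the operator set this architecture
  needs; it is not a general framework.
- Checkpoints are NumPy `.npz` archives of named tensors; no interchange
  with other frameworks' formats.
- The attention trace stores batched arrays; single-image shapes are the
  documented per-item view.
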