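# Methods

This note records the modelling assumptions, numerical conventions and
deliberately-made design choices behind `agenas`, in the order a reader
meets them: the age model, the two search engines, the complexity
accounting, the synthetic data, and the desk-scale problem sizes the
test suite runs at.

## Age model

Ages are treated as 76 ordinal classes (integer years 0–75). The
network's softmax distribution over the labels is trained with
cross-entropy against label-smoothed one-hot targets (ε = 0.1 by
default); the predicted age is the distribution's expectation, which is
continuous and always inside [0, 75] by convexity. Expectation-based
reading of a categorical head is well established for facial and dental
age estimation; its known bias is compression toward the label-range
center for very young and very old subjects, visible in the per-decade
MAE report.

Source populations reach ages above 75 while the label space stops
there; inputs with larger ages are clamped to the top label and a
warning is logged. This is a policy of this package, chosen over
widening the label space so that the expectation head and the published
76-way output shape stay aligned.

Mirror inference averages the predicted ages of an image and its
horizontal flip (panoramic radiographs are approximately bilaterally
symmetric). For a symmetric input this equals the plain prediction
exactly, which is the invariant the tests pin.

Training defaults follow the common fine-tuning recipe for this task:
Adam, batch 16, learning rate 1e-4, 100 epochs, augmentation by
horizontal flip (p = 0.5), isotropic scaling U(0.9, 1.1) and translation
of up to ±5% of the image side. The augmentation magnitudes are this
package's choice; only the transform family is prescribed by the task.
An optional cosine learning-rate schedule is provided and used by the
desk-scale runs, which train far fewer steps than the full recipe.

## Differentiable cell search

Cells are DAGs with 2 input nodes, 4 intermediate nodes (2 in the toy
configurations) and a concatenated output. Mixed edges weight the 11
candidate operators by softmax(α). Partial channel connections pass a
sampled fraction (default 1/4) of each edge's channels through the
mixture and bypass the rest unchanged; the mask is resampled uniformly
per forward pass from the run's seeded generator. On strided
(reduction-cell) edges the bypass channels are 2×2 average-pooled so the
two groups reassemble at a common resolution — a numerical choice this
package makes; identity bypass is only well defined at stride 1. Edge
normalization multiplies each incoming edge by softmax(β) over the
target node's incoming edges.

Group-convolution operators use groups = 9, so mixtures require the
sampled channel count to be divisible by 9 — satisfied by the standard
channel settings (36 × 1/4 = 9, 54 divisible by 9 at larger widths).

The bilevel loop is first-order: alternating momentum-SGD steps on the
network weights (lr 0.1, batch 16, weight decay 1e-4, 60% split) and
Adam steps on (α, β) (lr 6e-4, weight decay 1e-3, 40% split).
Second-order gradient correction is out of scope. Discretization:
per edge the argmax non-zero operator; per node the two incoming edges
with the largest softmax(β) × (best operator weight); ties break toward
the lower source index. The zero operator can never be selected.

The evaluation network stacks 8 cells (5 normal, 3 reduction at
1-indexed slots 1, 3, 6) behind a two-stage strided stem; with the three
reductions the output grid is input/32. Initial channels 36 and 54 give
the Small and Large variants.

## One-shot supernet search

The supernet has 16 choice layers between a strided stem and a
classifier head; each layer holds three independently parameterized
blocks (MBConv-3×3, MBConv-5×5, parallel-asymmetric) sharing the layer's
(cin, cout, stride, expand). Every block keeps its expand convolution
even at expand ratio 1 so each block is exactly 3 weighted stages.
Training activates one uniformly sampled path per mini-batch and updates
only its parameters plus the shared stem/head (momentum SGD 0.9, lr 0.1
with cosine decay, weight decay 4e-5, batch 64, label smoothing 0.1;
20,000 mini-batches at full scale, far fewer at desk scale).

The parallel-asymmetric block splits the expanded channels into two
complementary halves convolved depthwise with 1×7 and 7×1. The split
into *complementary* halves (rather than both branches seeing the same
half) is this package's choice; it is the wiring whose depthwise cost is
exactly 7 taps per expanded channel, matching the closed form. The
sequential alternative (1×7 then 7×1 on all channels) would cost 14.

The discrete search stage is evolutionary — population 50, 20
generations, single-point crossover (p = 0.5), per-locus mutation
(p = 0.1), elitist top-k — because the one-shot framework leaves the
search algorithm free; candidates violating the MAC budget are never
evaluated, and an infeasible budget raises an explicit error. On spaces
small enough to enumerate, the tests require the evolutionary result to
match brute force.

### The packaged AGE-SPOS plan

The published description of the searched lightweight network fixes its
global structure (16 blocks, depth 50, half the blocks
parallel-asymmetric, widths 0.5×/1.0×/1.5×, 76-way head) and its
complexity at each width, but not the per-layer channel schedule or the
block order. The packaged plan is therefore a **reconstruction**: an
MBConv-style monotone schedule (stem 32; block widths 16→304; expand
ratios in {1, 3, 4, 6}; stride-2 at blocks 3, 4, 7, 10; fixed 1152-wide
pre-classifier convolution) calibrated by simulated annealing so the
package's own counter reproduces the published FLOPs/parameter pairs at
all three widths simultaneously (max deviation 0.6%). Width scaling
multiplies block widths and rounds to multiples of 8; the head width is
fixed across widths — the published parameter counts grow distinctly
sub-quadratically in width, which is only consistent with a fixed-width
head. The packaged path alternates MB3 / asym / MB5 / asym, satisfying
the 8-of-16 structural fact; the true block order is not recoverable
from the published description.

Squeeze-excitation gates (pooled bottleneck, reduction 4, biased FC
stages, placed between the depthwise stage and the projection) are
off by default — consistent with the published ablation's conclusion —
but fully counted and constructible for ablation experiments.

## Complexity accounting

One multiply-accumulate = one FLOP. Counted: convolutions (divided by
groups) and fully connected layers, including the squeeze-excitation
bottleneck. Not counted: normalization, activations, pooling,
element-wise adds, biases. Parameters count every learnable scalar
including normalization affine pairs; whether published tables included
those is unknowable, hence the 5% tolerance the acceptance checks use.
"Same" padding everywhere: spatial size n maps to ceil(n/s).

Depth counts weighted *stages*: parallel branches inside a block count
once (so every supernet block is 3), a squeeze-excitation gate is not a
stage, and the classifier (pre-classifier pointwise conv + global pool +
fully connected) is one stage. This is the convention under which the
16-block network is exactly 1 + 48 + 1 = 50 layers deep.

The closed-form block costs count exactly the three convolution stages
of a stride-1 block at output resolution h×w; the tests require them to
equal the counter's layer-by-layer enumeration to the last integer on
200 random configurations.

## Synthetic pseudo-OPGs

The generator renders 8-bit grayscale phantoms (square, default 64 px;
the pipeline resizes real data to 384×384, and square reduced-scale
rendering loses nothing the tests need). Two opposing tooth rows on a
shallow arch over a darker mandible band; four ageing signs map to
monotone proxies: tooth count ramps 8→28 over ages 0–12 (eruption),
crown height shrinks linearly (abrasion), the dark pulp core shrinks
(secondary dentin), and root brightness/gradient increases
(transparency). Each feature gets ±5% per-sample jitter so the features
are informative but not deterministic given age; ordinary least squares
of age on the four rendered features exceeds R² = 0.9 by construction.
Additive Gaussian noise (sd 0.05 by default, in [0, 1] intensity units)
approximates detector noise. The age sampler is either uniform or a
discretized log-normal with median 27 (σ = 0.55), matching the
right-skewed demographics of clinical OPG archives.

What the phantoms do **not** emulate: trabecular bone texture,
projection/ghosting artifacts, restorations and pathology, sex
differences, and the saturating information content of real adult
dentition. Passing the end-to-end tests therefore demonstrates that the
pipeline can extract monotone morphological signals — not that any
architecture reaches clinical accuracy.

## Desk-scale problem sizes

The package's own runtime is a NumPy reverse-mode autodiff; all training
in the test suite is sized for a single CPU, as a deliberate choice of
test scale:

* end-to-end learnability: 2,000 phantoms at 64×64, a 5-block path
  network (~21k parameters), 10 epochs, batch 32, Adam 3e-3 without
  augmentation; held-out MAE must fall below 8 years against ~19 for
  the best constant predictor;
* supernet checks: 2–4 layer plans at 16–32 px with exhaustive path
  enumeration as the oracle;
* cell-search checks: 1–2 cells, 2 intermediate nodes, 12–16 px inputs;
  the informative-operator check optimizes a single mixed edge where
  the target equals one operator's output exactly.

Known limitations: the bilevel loop is first-order only; supernet
batch-norm statistics are shared across paths (standard one-shot
practice, a known source of ranking noise); the expectation head
under-covers the age extremes; and the packaged AGE-SPOS schedule is a
calibrated reconstruction, not the original network's weights or exact
layout.
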