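# Methods

## Model family and execution semantics

A network is a sequence of convolutional blocks followed by a global
average-pool + dense softmax readout. All convolutions are stride 1 with
zero-filled "same" padding (the printed spatial bookkeeping of the family —
128 → 2 over six pooling stages — requires size-preserving convolutions);
max pooling is 2×2 stride 2, with odd extents padded by −∞ so the output is
⌈n/2⌉. Recurrent (BL-style) layers add a lateral convolution from the same
layer's activations one step earlier. The lateral state at t = 0 is the
all-zero stack, which makes step 1 exactly the bottom-up sweep — a property
the tests rely on. Batch normalisation is applied per time step with
independent gain and shift; running statistics are tracked per step and used
at evaluation.

Unrolling follows "engineering" time (feedforward edges take no time, lateral
edges one step). For lateral-only recurrence this is node-for-node equivalent
to "biological" time, in which every edge takes one tick and layer n at tick
k computes the engineering activation (n, t = k − n + 1); `rvt.unroll`
builds both graphs and `run_biological` executes the tick-by-tick schedule as
an independent code path, which the tests compare against the engineering
forward pass to 1e-6.

There is no separate convolution bias: the batch-norm shift β plays the role
of the per-layer bias term. This is also the parameter-counting convention
(below). The implementation is pure numpy, with hand-written
backpropagation-through-time verified against central finite differences in
the test suite; there is no framework dependency and no GPU path, so the
intended operating regime is reduced scale (a few blocks, ≤ 32×32 inputs).

## Counting conventions

**Parameters.** Trainable parameters are convolution weights, batch-norm
gain/shift (2 per feature map per time step), and the readout's weights and
bias; running statistics are excluded, and convolutions carry no separate
bias (β is the shift). Under this convention the full-scale family counts to
B 11.0M, B-K 39.8M, B-F 40.0M, BL 28.9M and B-U 212.7M; the extra
normalisation parameters BL accrues over steps 2–8 total 59,584 ≈ 60k. B-D
counts to 28,819,848 ≈ 28.8M — about 0.2% below BL — so "parameter-matched"
is approximate for the depth control; no counting variant we examined
(explicit conv biases, counting running statistics) moves B-D to BL's rounded
value without breaking the other totals. An optional `conv_bias=True` flag
restores explicit biases for sensitivity analyses.

**FLOPs.** One multiply–add counts as 2 floating-point operations. By
default only convolution and dense multiply–adds are counted; pooling
comparisons, normalisation and element-wise operations are available behind
flags, and every cost output carries the convention tag. Lateral products
with the zero initial state are counted by default (per-step cost constant in
t); `skip_zero_lateral` omits them. Comparative analyses (matched-cost
threshold selection, SAT orderings) are ratios/orderings and hence
convention-invariant.

## Decision mechanism

Entropy is Shannon entropy in **nats** (divide by ln 2 for bits); outputs are
tagged with the unit. The threshold comparison is inclusive (entropy ≤ θ),
so θ = ln C stops every image at step 1, and an unreached threshold falls
back to the final step. The default readout is cumulative (the running mean
of per-step distributions), which is also the readout whose accuracy the
training log reports; argmax ties break toward the lowest class index. The
SAT threshold grid defaults to the sorted unique entropies observed in the
evaluation set plus 0 and ln C, so every achievable operating point appears;
matched-cost selection breaks ties toward the larger (cheaper) threshold.
Decisions are measured post hoc on the full unrolled run — there is no
dynamically halting graph.

## Training recipe

Adam (learning rate 0.005, epsilon 0.1), L2 coefficient 1e-6, constant
learning-rate schedule, batch 100, 90 epochs are the full-scale defaults;
desk-scale runs override epochs/batch. The loss is the mean over readouts of
the batch cross-entropy. Preprocessing crops (training: random crop of at
least one third of the image area with aspect ratio in [3/4, 4/3], random
left-right flip, brightness ±0.1 and saturation/contrast ×[0.9, 1.1] jitter —
the jitter magnitudes are our choices for the unquantified "small
distortions"; evaluation: centre crop), resizes, and rescales [0, 1] →
[−1, 1]. Initialisation is fan-in variance scaling for convolutions and
Glorot-uniform for the readout, seed-controlled throughout; two runs with the
same seed are bit-identical.

## Reaction-time pipeline

Eight readout sites are the existing per-step readouts for multi-readout
models; for single-readout models a candidate layer list is reduced to eight
sites by dynamic programming that minimises the maximum deviation of
between-site cumulative-cost gaps from the even spacing total/8, always
keeping the final (full-computation) candidate. Activations are projected to
512 dimensions by PCA fitted on training images with all sites pooled
(randomised solver, seeded; an identity-with-padding map when the ambient
dimension is already ≤ 512). The binary readout y_t = σ(α y_{t−1} + w·p_t +
b) starts from the neutral y_0 = 0.5 and shares (α, w, b) across sites for
recurrent models; feedforward models get an independent static readout per
site (α absent). It is trained full-batch with Adam, learning rate 0.001,
1000 iterations, binary cross-entropy weighted inversely to class frequency
and averaged across sites. Sigmoid outputs are averaged across model seeds
*before* the two-outcome entropy is computed (the averaging stage is a free
choice; averaging probabilities is the smoothest of the candidates).

Threshold fitting is double leave-one-out: every fold removes one subject
(all images) and one image (all subjects); θ maximises the Pearson
correlation between network reaction times and the training subjects' mean
reaction time on training images, over the grid of entropies observed on
training images plus endpoints {0, ln 2}; ties go to the largest θ (earliest
decisions). Folds with undefined correlations fall back to the global median
of fitted thresholds and are counted; an entirely constant human matrix is an
error. Repeated presentations are averaged per (subject, image) before
fitting, and error trials are not excluded.

A structural caveat documented here because it bounds attainable recovery:
with continuously distributed entropies, the image owning the entropy value
immediately bracketing the true threshold is necessarily mispredicted in the
fold that holds it out — no training data can resolve thresholds within the
final grid plateau. Zero-noise parameter-recovery simulations therefore
plateau at ~95/96 exactly predicted cells (per-subject r ≈ 0.9986), while
the fitted threshold itself is recovered within one grid step in ≥ 99% of
folds.

Per-subject correlations between models are compared with a two-tailed paired
sign-flip permutation test (10,000 permutations, identity included, so
p ≥ 1/10,001) and Benjamini–Hochberg FDR control; accuracy comparisons use
McNemar's test (exact binomial below 25 discordant pairs, else the
continuity-corrected chi-square (|b−c|−1)²/(b+c) — the switch point is our
documented rule) with Bonferroni correction. The noise ceiling is
lower-bounded by leave-one-subject-out human consistency.

## Synthetic data

The image task stands in for a large-scale recognition dataset: 10 classes
(default), each a procedurally drawn prototype (distinct shape and colour on
a mid-grey 32×32 canvas), corrupted by additive Gaussian pixel noise whose
standard deviation — the image's difficulty — is uniform on [0, 0.8]. The
first/second half of the classes form the binary super-category partition.
At difficulty 0 a nearest-prototype classifier is perfect, and reference
accuracy decreases across difficulty bins, so entropy-threshold reaction
times vary across images. What this generator does **not** emulate: natural
image statistics, within-class variation (pose, clutter, scale), or
label noise — so passing tests demonstrate the machinery (gradients,
decision logic, fitting, recovery), not naturalistic performance levels.

Synthetic subjects respond to image i in gain_s · site(θ*, i) + offset_s
milliseconds plus Gaussian trial noise, averaged over 6 repeats, for 20
subjects × 96 images by default (gain ~ N(100, 15) ms/site, offset ~
N(450, 50) ms, trial noise 80 ms — values chosen to give realistic ~500–1300
ms reaction times and a noise ceiling well inside (0, 1)). The planted
threshold θ* (default 0.35 nats) must lie in (0, ln 2). Reference entropy
trajectories emulate averaged sigmoid readouts with per-image evidence rates,
giving graded reaction times without requiring a trained network.

## Problem sizes used by the tests

Trained-model tests use a two-block BL (8 and 16 feature maps, 3×3 kernels,
T = 4) on the default synthetic task (400 training / 100 validation images),
30 epochs, three seeds — enough for validation accuracy ≈ 0.7 at the final
step, clearly above the 0.1 chance level, with rising per-step accuracy and a
usable entropy range. The "mid-range" threshold in the difficulty ↔
reaction-time check is the median observed final-step entropy: at thresholds
outside the achievable range reaction times are constant and the correlation
undefined. Gradient checks and unrolling-equivalence fixtures use 2-layer,
3-step networks on 6×6 inputs.

## Known limitations

- Desk scale only: no GPU, no data pipeline for natural images; full-scale
  accuracies are out of scope by design.
- B-D's printed parameter match to BL is approximate (28.8M vs 28.9M under
  our counting convention).
- The biological-time executor covers lateral-only recurrence; top-down
  connections (which would break the engineering/biological equivalence) are
  not modelled.
- The FLOP convention is declared rather than canonical; absolute costs are
  comparable only within a convention.
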