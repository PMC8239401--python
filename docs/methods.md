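# Methods

## Problem setting

A bidirectional TSS pair is summarized by a fixed-length window centered on
the midpoint between the two divergent TSSs: 500 bp (flank 250) for
stability-annotated US/UU pairs, 600 bp (flank 300) for CAGE-defined
elements. Windows are oriented so the sense (stable) TSS points in the +x
direction; midpoint-relative coordinates run from −l/2 to l/2−1, and "the
+20..+120 bp downstream region" is the half-open slice [+20, +120) in this
frame. Coordinates are 0-based half-open (BED convention) throughout.
Whether the original real-data windows were reverse-complemented to a
canonical orientation is not derivable from the data we model; we fix the
convention above and generate synthetic data in it.

The promoter class (US) is the positive label (1), enhancers (UU) negative
(0). One-hot channels are ordered (A, C, G, T); an uncalled base N encodes
as an all-zero row, so each row's sum equals the number of called bases at
that position. This keeps channel semantics under gradient analysis; the
synthetic generator never emits N.

## Classifier

The architecture family is conv(n₁, w₁) → ReLU → dropout → max-pool p₁ →
conv(128, 5) → ReLU → dropout → max-pool p₂ → dense(512, ReLU) → dropout →
dense(1) → sigmoid, with stride-1 same-padded convolutions and pool stride
equal to the pool window. The coupling constraint p₁·p₂ = 100 (with l
divisible by 100) fixes the flattened hidden-layer input at (l/100)·128 =
640 for l = 500 across all seven pool pairs, which is asserted at build
time. Models are named CNN-p₁, with the first-layer filter count in
parentheses when it differs from 30 and the filter size as a subscript-like
prefix when it differs from 19 (e.g. CNN_9-10(90)).

Training: binary cross-entropy
L = −(1/N) Σᵢ [zᵢ log yᵢ + (1−zᵢ) log(1−yᵢ)] (z true, y predicted — note
we keep the conventional roles; some descriptions of this loss swap the
symbols), mini-batch size N = 30, exactly 40 epochs, no early stopping,
dropout probability 0.5 active only in training, Adam with learning rate
3·10⁻⁴. "Learning-rate decay 10⁻⁶" is implemented as the per-update
multiplicative schedule lr_t = lr/(1 + decay·t) — the convention of the
framework generation this training regime comes from; per-epoch decay is
the plausible alternative and the parameter is exposed. Weights are
Glorot-uniform initialized from a seeded generator; initialization, dropout
masks and epoch shuffling all derive from the training seed, so runs are
bit-reproducible. The engine is pure numpy (im2col convolutions); default
dtype float32, float64 available for gradient checking.

Predictions are clipped only inside the loss (machine-epsilon margins);
AU-ROC uses the Mann–Whitney tie convention (half credit), computed via
scikit-learn and checked in the tests against an exhaustive pairwise
oracle.

## Evaluation protocol

A stratified 90/10 hold-out split precedes fivefold cross-validation on the
90%. The train-side total is round-half-up of 0.9n, with per-class counts
by largest-remainder allocation so the stratified counts sum exactly to
that total (for 65,765 = 27,227 + 38,538 this gives 59,189/6,576; for
6,862 = 1,884 + 4,978 it gives 6,176/686). Folds are assigned round-robin
over class-grouped shuffled indices, so total and per-class fold sizes both
differ by at most one (6,176 → 1236, 1235, 1235, 1235, 1235). Each
fold-model is scored on its validation fold and on the common hold-out
set; the model-selection metric is the mean of the two mean AUCs.
Stratification is our choice (the 1,884/4,978 class imbalance makes
unstratified folds noisy); so is re-using one seeded shuffle for both
splits.

## Saliency

For a trained model the class score S(X) (pre-sigmoid logit — gradients of
the post-sigmoid probability differ only by a positive per-sequence factor
σ′, which normalization removes; taking them on the logit keeps the map
independent of output-bias shifts, which is asserted as a property) is
linearized around the input, S(X) ≈ wᵀX + b, with w obtained by one
backward pass. The raw importance of position i is |w at the observed
channel|; a max-over-channels variant is available behind a flag. Raw
scores are normalized to sum to 1 per sequence; the degenerate all-zero
gradient maps to the uniform 1/l. Important positions are those strictly
above 1/l (0.002 at l=500, 1/600 ≈ 0.00167 at l=600). Aggregate maps stack
normalized scores over the top-predicted promoters (probability > 0.95,
at most 50, descending). Dropout is disabled during saliency computation.

Gradients are verified two ways: against central finite differences at
ε = 10⁻⁶ on small float64 networks (agreement ~10⁻⁹ relative), and at
ε = 10⁻³ across the whole architecture family, where positions whose two
one-sided slopes disagree are excluded — there the perturbation straddles
a ReLU/max-pool kink and a first-order comparison is undefined.

## Hexamer SVM baseline

Hexamer vectors have dimension 4⁶ = 4096, indexed lexicographically over
A<C<G<T; counting slides a stride-1 window, skips windows containing N,
and divides by the number of counted windows. The classifier is an RBF
SVM; C and γ range over integer exponents −3..1 and −13..−1. The exponent
base is not derivable from the ranges alone; we use base 2, the dominant
convention for RBF grids (configurable). Grid scoring uses the same
stratified fivefold protocol; ties resolve to the first grid point in
iteration order, making reruns deterministic. Features enter the kernel as
raw frequencies without further scaling.

## GC statistics

GC = (G+C)/(A+T+G+C); N counts in neither numerator nor denominator, and
an empty effective position set yields a missing value rather than zero.
Slice GC is the arithmetic mean of per-sequence fractions. GC at
saliency-important positions is pooled (total G+C over total counted bases
across the group) because important sets vary in size per sequence; the
mean-of-fractions alternative is also reported per sequence in the
`GCReport`.

## Synthetic generator

The generator emulates exactly the compositional structure the analyses
measure. Defaults: 500-bp windows; promoter class global GC 0.63, enhancer
0.50; downstream [+20, +120) GC 0.67 vs 0.51; TSS spacing drawn from a
normal with means 120 bp (promoter) and 91 bp (enhancer), sd 30, clipped to
[10, 400] and recorded as metadata only (sequence content does not depend
on it). Sites are independent; G/C and A/T each split their totals evenly.
Positions outside the downstream slice use a flank GC solved so the
whole-window expectation equals the global parameter (0.62 and 0.4975 at
the defaults); an infeasible combination (flank outside (0,1)) is a fatal
error reporting the required value. Optional consensus motifs are planted
at uniform offsets within a window, per class, with recorded positions.
Identical spec and seed give byte-identical output files.

What the generator does *not* emulate: dinucleotide/CpG clustering, real
TF-binding motifs, spacing-dependent sequence content, CAGE/GRO-seq signal,
and any coupling between positions. Passing the end-to-end tests therefore
shows the pipeline detects and localizes compositional class signal under
its own assumptions, not that real promoters and enhancers are separable at
any particular AUC.

## End-to-end experiments and problem sizes

The end-to-end suite and `scripts/acceptance.py` run three experiments,
sized for a single CPU core:

* **Default signal** — 1000 sequences/class, CNN-10(90), 40 epochs:
  hold-out AUC, then saliency of the top-predicted promoters; downstream
  [+20,+120) vs upstream [−250, 0) mean compared by a one-sided sign test,
  and pooled important-position GC compared to enhancer whole-window GC.
* **Null control** — identical GC parameters for both classes (all 0.5),
  1000/class, base CNN-10: hold-out AUC should sit in the chance band.
* **Positional-only signal** — matched global GC 0.55 for both classes,
  downstream 0.67 vs 0.51, 300/class: CNN-10(90) hold-out AUC compared to
  the hexamer SVM tuned over the full 65-point grid. The positional signal
  reaches the position-free hexamer representation only through the
  mixture composition, so the CNN is expected to do at least as well.

## Known limitations

* No GPU path; large sweeps (seven pools × fivefold at realistic n) are
  hours, not minutes, on one core.
* The independent-site generator makes the classification easier than real
  data; reported synthetic AUCs near 1.0 say nothing about real-data AUCs.
* Adam decay semantics and the SVM exponent base are conventions chosen,
  not recovered facts; both are configurable.
* Saliency is a first-order method: scores at positions inside strongly
  saturated ReLU regions are legitimately zero even when the base matters
  combinatorially.
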