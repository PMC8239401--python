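# regseq-tss

Promoters and enhancers are both transcribed bidirectionally from closely
spaced, divergent transcription start sites (TSSs), yet they behave very
differently: promoters produce a stable mRNA in the sense direction
(an unstable–stable, "US", TSS pair), while enhancers produce unstable
RNA in both directions ("UU" pairs). `regseq-tss` is a toolkit for asking
what in the DNA sequence around the shared TSS midpoint distinguishes the
two. It is aimed at regulatory-genomics researchers who want to train a
sequence-level classifier on fixed windows around bidirectional TSS
midpoints and then interrogate *where* in the window the discriminative
signal lives.

## What it does

* **Convolutional classifier.** Fixed-length windows (500 or 600 bp,
  one-hot encoded with channels A/C/G/T) are classified
  promoter-vs-enhancer by a two-convolutional-layer network:
  conv(n₁ filters, width w₁) → ReLU → max-pool p₁ → conv(128, width 5) →
  ReLU → max-pool p₂ → dense(512, ReLU) → sigmoid. The pool windows are
  coupled, p₁·p₂ = 100, so the flattened input to the hidden layer is
  (l/100)·128 for every member of the family — the pool-size sweep
  {(1,100), (2,50), (4,25), (10,10), (25,4), (50,2), (100,1)} varies
  down-sampling without varying hidden-layer capacity. Training is
  mini-batch (30) Adam, learning rate 3·10⁻⁴ with per-step decay 10⁻⁶,
  dropout 0.5, binary cross-entropy, exactly 40 epochs; evaluation is
  AU-ROC under fivefold cross-validation after a stratified 90/10
  hold-out split. The engine is pure numpy (no GPU needed) and
  bit-reproducible given a seed.
* **Gradient saliency maps.** For a trained model the per-nucleotide
  importance is the absolute gradient of the pre-sigmoid score at the
  observed channel (first-order Taylor expansion S(X) ≈ wᵀX + b),
  normalized to sum to 1 per sequence; a position is "important" when its
  normalized score exceeds the uniform level 1/l (0.002 at l=500).
* **Hexamer-SVM baseline.** Sequences as 4096-dimensional hexamer
  frequency vectors, RBF SVM tuned by grid search over C = 2⁻³…2¹ and
  γ = 2⁻¹³…2⁻¹ (integer exponents, 65 points) with the same CV protocol.
* **GC characterization.** GC = (G+C)/(A+T+G+C) per window, per
  midpoint-relative slice (e.g. the +20..+120 bp region downstream of the
  sense TSS), and pooled over saliency-called important positions.
* **Synthetic data.** A generator that emulates the US/UU sequence
  structure: class-dependent global GC (63% vs 50%), extra GC elevation in
  +20..+120 (67% vs 51%), TSS-spacing metadata (mean 120 vs 91 bp), and
  optional planted consensus motifs — so the whole pipeline is testable
  without restricted genomic data.

## Worked example

```python
import numpy as np
from regseq_tss import (SyntheticSpec, generate_dataset, ArchitectureSpec,
                        TrainingSpec, train_model, predict, compute_auroc,
                        select_top_predictions, compute_saliency_batch,
                        aggregate_saliency)
from regseq_tss.cnn_model import holdout_split
from regseq_tss.sequence_io import labels_of

ds = generate_dataset(SyntheticSpec(n_promoter=1000, n_enhancer=1000, seed=1))
labels = labels_of(ds.sequences)
tr, te = holdout_split(labels, 0.1, np.random.default_rng(0))
train = [ds.sequences[i] for i in tr]; test = [ds.sequences[i] for i in te]

model = train_model(train, ArchitectureSpec(n_filters_1=90),  # "CNN-10(90)"
                    TrainingSpec(seed=0))
print("hold-out AUC:", compute_auroc(labels_of(test), predict(model, test)))

top = select_top_predictions(model, test, prob_min=0.95, top_n=50)
agg = aggregate_saliency(compute_saliency_batch(model, top))
print("mean saliency +20..+120:", agg.region_mean(20, 120))
print("mean saliency -250..0:  ", agg.region_mean(-250, 0))
```

Output (~3 min on one CPU):

```
hold-out AUC: 1.0
mean saliency +20..+120: 0.0025724719139723156
mean saliency -250..0:   0.0019902601563326415
```

The classes are cleanly separable (the generator's global GC difference is
a strong signal), and the saliency mass concentrates on the +20..+120 bp
downstream region where the generator plants the extra promoter-class GC
elevation — the uniform baseline would be 1/500 = 0.002 everywhere.

The same stages are available from the shell:

```bash
regseq-tss simulate --out data/ --seed 1
regseq-tss train --config train.yaml --model-out model.npz --cross-validate
regseq-tss saliency --model model.npz --fasta data/sequences.fa \
    --labels data/labels.tsv --out saliency.tsv
regseq-tss baseline --fasta data/sequences.fa --labels data/labels.tsv \
    --out svm.json
regseq-tss gcstats --fasta data/sequences.fa --slice 20:120 --out gc.tsv
```

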