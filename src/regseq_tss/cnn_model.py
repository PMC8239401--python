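"""The constrained two-convolutional-layer architecture family and its
training/evaluation protocol.

The family is parameterized by the first-layer filter count/size and a
coupled pair of max-pool windows whose product is fixed at 100. Because both
convolutions are same-padded and pooling strides equal the windows, the
flattened input to the hidden layer has size ``(l/100) * n_filters_2`` for
every legal pool pair — architecture capacity upstream of the hidden layer
varies while the hidden layer itself is held fixed, which is what makes the
pool-size sweep a controlled experiment.

Training follows a fixed regime: mini-batch gradient descent (batch 30) with
Adam (lr 3e-4, per-step decay 1e-6), dropout 0.5 after each convolution and
the hidden layer, binary cross-entropy loss, exactly 40 epochs, no early
stopping. Evaluation is AU-ROC under fivefold cross-validation after a
stratified 90/10 hold-out split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .network import Adam, Conv1D, Dense, Dropout, Flatten, MaxPool1D, Network, ReLU
from .sequence_io import EncodedSequence, labels_of, stack_onehot

logger = logging.getLogger(__name__)

#: The seven coupled max-pool pairs of the pool-size sweep.
POOL_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 100), (2, 50), (4, 25), (10, 10), (25, 4), (50, 2), (100, 1),
)

POOL_PRODUCT = 100


@dataclass(frozen=True)
class ArchitectureSpec:
    """One member of the constrained CNN family.

    Defaults are the base model: 30 first-layer filters of size 19,
    pool pair (10, 10), 128 second-layer filters of size 5, 512 hidden units.
    """

    input_length: int = 500
    n_filters_1: int = 30
    filter_size_1: int = 19
    pool_1: int = 10
    n_filters_2: int = 128
    filter_size_2: int = 5
    pool_2: int = 10
    hidden_units: int = 512

    def validate(self) -> None:
        if self.pool_1 * self.pool_2 != POOL_PRODUCT:
            raise ValueError(
                f"max-pool windows ({self.pool_1}, {self.pool_2}) must have "
                f"product {POOL_PRODUCT}"
            )
        if self.input_length % POOL_PRODUCT:
            raise ValueError(
                f"input length {self.input_length} must be divisible by "
                f"{POOL_PRODUCT}"
            )
        if self.input_length % self.pool_1:
            raise ValueError("first pool window must divide the input length")

    @property
    def hidden_input_size(self) -> int:
        """Flattened size entering the hidden layer; pool-pair invariant."""
        return (self.input_length // POOL_PRODUCT) * self.n_filters_2

    @property
    def name(self) -> str:
        """Model naming: CNN-<pool_1>, with filter count/size qualifiers."""
        base = f"CNN-{self.pool_1}"
        if self.filter_size_1 != 19:
            base = f"CNN_{self.filter_size_1}-{self.pool_1}"
        if self.n_filters_1 != 30:
            base += f"({self.n_filters_1})"
        return base


@dataclass(frozen=True)
class TrainingSpec:
    """The fixed training regime; only the seed routinely varies."""

    batch_size: int = 30
    epochs: int = 40
    dropout_p: float = 0.5
    learning_rate: float = 3e-4
    lr_decay: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class EvalReport:
    """Cross-validation summary in the shape of one sweep-table row."""

    arch: ArchitectureSpec
    fold_val_auc: list[float]
    fold_holdout_auc: list[float]

    @property
    def mean_val_auc(self) -> float:
        return float(np.mean(self.fold_val_auc))

    @property
    def sd_val_auc(self) -> float:
        return float(np.std(self.fold_val_auc, ddof=1))

    @property
    def mean_holdout_auc(self) -> float:
        return float(np.mean(self.fold_holdout_auc))

    @property
    def sd_holdout_auc(self) -> float:
        return float(np.std(self.fold_holdout_auc, ddof=1))

    @property
    def combined_auc(self) -> float:
        """Mean of validation and hold-out AUC — the model-selection metric."""
        return 0.5 * (self.mean_val_auc + self.mean_holdout_auc)

    def summary(self) -> dict:
        return {
            "model": self.arch.name,
            "val_auc": f"{self.mean_val_auc:.3f} ± {self.sd_val_auc:.3f}",
            "holdout_auc": f"{self.mean_holdout_auc:.3f} ± {self.sd_holdout_auc:.3f}",
            "combined_auc": round(self.combined_auc, 4),
        }


def build_architecture(spec: ArchitectureSpec, seed: int = 0,
                       dropout_p: float = 0.5, dtype=np.float32) -> Network:
    """Instantiate a network for ``spec``: conv-relu-drop-pool twice, then a
    ReLU hidden layer with dropout and a single sigmoid output unit."""
    spec.validate()
    rng = np.random.default_rng(seed)
    layers = [
        Conv1D(4, spec.n_filters_1, spec.filter_size_1, rng, dtype),
        ReLU(),
        Dropout(dropout_p, rng),
        MaxPool1D(spec.pool_1),
        Conv1D(spec.n_filters_1, spec.n_filters_2, spec.filter_size_2, rng, dtype),
        ReLU(),
        Dropout(dropout_p, rng),
        MaxPool1D(spec.pool_2),
        Flatten(),
        Dense(spec.hidden_input_size, spec.hidden_units, rng, dtype),
        ReLU(),
        Dropout(dropout_p, rng),
        Dense(spec.hidden_units, 1, rng, dtype),
    ]
    net = Network(layers)
    net.spec = spec  # type: ignore[attr-defined]
    return net


def binary_cross_entropy(true_labels: np.ndarray, predicted: np.ndarray,
                         eps: float = 1e-12) -> float:
    """Mean binary cross-entropy, predictions clipped away from {0, 1}."""
    z = np.asarray(true_labels, dtype=np.float64)
    y = np.asarray(predicted, dtype=np.float64)
    if z.shape != y.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {y.shape}")
    y = np.clip(y, eps, 1.0 - eps)
    return float(-np.mean(z * np.log(y) + (1.0 - z) * np.log(1.0 - y)))


def _require_both_classes(labels: np.ndarray, context: str) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError(f"{context}: both classes must be present")


def train_model(train: Sequence[EncodedSequence], arch: ArchitectureSpec,
                tr: TrainingSpec) -> Network:
    """Train one network for exactly ``tr.epochs`` epochs.

    Weight initialization, dropout masks and per-epoch shuffling all derive
    from ``tr.seed``, so two runs on identical inputs produce identical
    parameters.
    """
    arch.validate()
    tr.validate()
    x = stack_onehot(train)
    z = labels_of(train).astype(np.float32)
    _require_both_classes(z, "train_model")
    if x.shape[1] != arch.input_length:
        raise ValueError(
            f"sequence length {x.shape[1]} != architecture input length "
            f"{arch.input_length}"
        )
    net = build_architecture(arch, seed=tr.seed, dropout_p=tr.dropout_p)
    opt = Adam(net.params, lr=tr.learning_rate, decay=tr.lr_decay)
    rng = np.random.default_rng(tr.seed + 1)  # shuffling stream
    n = x.shape[0]
    for epoch in range(tr.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tr.batch_size):
            idx = order[start : start + tr.batch_size]
            xb, zb = x[idx], z[idx]
            score = net.score(xb, train=True)
            y = 1.0 / (1.0 + np.exp(-score.astype(np.float64)))
            epoch_loss += binary_cross_entropy(zb, y) * len(idx)
            # d(mean BCE)/d(logit) = (y - z)/N
            net.backward(((y - zb) / len(idx)).astype(x.dtype))
            opt.step(net.grads)
        logger.info("epoch %d/%d loss %.4f", epoch + 1, tr.epochs, epoch_loss / n)
    return net


def predict(model: Network, sequences: Sequence[EncodedSequence],
            batch_size: int = 256) -> np.ndarray:
    """P(promoter) for each sequence, dropout disabled."""
    x = stack_onehot(sequences)
    spec = getattr(model, "spec", None)
    if spec is not None and x.shape[1] != spec.input_length:
        raise ValueError(
            f"sequence length {x.shape[1]} != model input length "
            f"{spec.input_length}"
        )
    out = [model.predict_proba(x[i : i + batch_size])
           for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(out)


def compute_auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AU-ROC; equals P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    _require_both_classes(labels, "compute_auroc")
    return float(roc_auc_score(labels, scores))


# -- splitting ------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def holdout_split(labels: np.ndarray, holdout_fraction: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified hold-out split with exact total train count.

    The train total is round-half-up of ``(1 - holdout_fraction) * n``;
    per-class train counts are allocated by largest remainder so that the
    stratified counts sum exactly to that total.
    """
    labels = np.asarray(labels)
    n = len(labels)
    n_train = _round_half_up((1.0 - holdout_fraction) * n)
    classes, _ = np.unique(labels, return_counts=True)
    targets = {c: (1.0 - holdout_fraction) * np.sum(labels == c) for c in classes}
    alloc = {c: int(np.floor(t)) for c, t in targets.items()}
    deficit = n_train - sum(alloc.values())
    for c in sorted(classes, key=lambda c: targets[c] - np.floor(targets[c]),
                    reverse=True)[:deficit]:
        alloc[c] += 1
    train_idx, test_idx = [], []
    for c in classes:
        idx = rng.permutation(np.flatnonzero(labels == c))
        train_idx.append(idx[: alloc[c]])
        test_idx.append(idx[alloc[c]:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(test_idx)))


def stratified_folds(labels: np.ndarray, k: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    """k folds, stratified, with total and per-class fold sizes differing
    by at most one (round-robin over class-grouped shuffled indices)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    ordered = np.concatenate(
        [rng.permutation(np.flatnonzero(labels == c)) for c in np.unique(labels)]
    )
    folds: list[list[int]] = [[] for _ in range(k)]
    for i, idx in enumerate(ordered):
        folds[i % k].append(int(idx))
    return [np.sort(np.asarray(f)) for f in folds]


def cross_validate(data: Sequence[EncodedSequence], arch: ArchitectureSpec,
                   tr: TrainingSpec, k: int = 5,
                   holdout_fraction: float = 0.1) -> EvalReport:
    """Stratified 90/10 hold-out split, then k-fold CV on the train part.

    Each fold-model is scored on its validation fold and on the common
    hold-out set; the report carries both AUC lists.
    """
    labels = labels_of(data)
    _require_both_classes(labels, "cross_validate")
    rng = np.random.default_rng(tr.seed)
    train_idx, test_idx = holdout_split(labels, holdout_fraction, rng)
    train_data = [data[i] for i in train_idx]
    test_data = [data[i] for i in test_idx]
    test_labels = labels_of(test_data)
    folds = stratified_folds(labels_of(train_data), k, rng)
    val_aucs, holdout_aucs = [], []
    for f, val_fold in enumerate(folds):
        val_mask = np.zeros(len(train_data), dtype=bool)
        val_mask[val_fold] = True
        fit = [s for s, m in zip(train_data, val_mask) if not m]
        val = [s for s, m in zip(train_data, val_mask) if m]
        model = train_model(fit, arch, replace(tr, seed=tr.seed + 100 + f))
        val_aucs.append(compute_auroc(labels_of(val), predict(model, val)))
        holdout_aucs.append(
            compute_auroc(test_labels, predict(model, test_data))
        )
        logger.info("fold %d: val AUC %.3f holdout AUC %.3f",
                    f + 1, val_aucs[-1], holdout_aucs[-1])
    return EvalReport(arch=arch, fold_val_auc=val_aucs,
                      fold_holdout_auc=holdout_aucs)


# -- sweeps ---------------------------------------------------------------


def pool_sweep(base: ArchitectureSpec = ArchitectureSpec()) -> list[ArchitectureSpec]:
    return [replace(base, pool_1=p1, pool_2=p2) for p1, p2 in POOL_PAIRS]


def filter_count_sweep(base: ArchitectureSpec = ArchitectureSpec(),
                       counts: Sequence[int] = (30, 60, 90, 120)
                       ) -> list[ArchitectureSpec]:
    return [replace(base, n_filters_1=c, pool_1=10, pool_2=10) for c in counts]


def filter_size_sweep(base: ArchitectureSpec = ArchitectureSpec(),
                      sizes: Sequence[int] = (9, 19, 29),
                      n_filters: int = 90) -> list[ArchitectureSpec]:
    return [replace(base, filter_size_1=s, n_filters_1=n_filters,
                    pool_1=10, pool_2=10) for s in sizes]


def sweep_family(input_length: int = 500) -> list[ArchitectureSpec]:
    """All twelve sweep members: 7 pool pairs, filter counts 60/90/120,
    filter sizes 9/29 at 90 filters."""
    base = ArchitectureSpec(input_length=input_length)
    family = pool_sweep(base)
    family += filter_count_sweep(base, counts=(60, 90, 120))
    family += filter_size_sweep(base, sizes=(9, 29))
    return family


def run_architecture_sweep(data: Sequence[EncodedSequence],
                           sweep: Sequence[ArchitectureSpec],
                           tr: TrainingSpec, k: int = 5,
                           holdout_fraction: float = 0.1) -> list[EvalReport]:
    """Cross-validate every architecture on the same data and seed."""
    for spec in sweep:
        spec.validate()
    return [cross_validate(data, spec, tr, k=k, holdout_fraction=holdout_fraction)
            for spec in sweep]


# -- persistence ----------------------------------------------------------


def save_model(model: Network, path) -> None:
    spec: ArchitectureSpec = model.spec  # type: ignore[attr-defined]
    np.savez(path,
             **{k: v for k, v in model.state_arrays().items()},
             **{f"spec_{f}": getattr(spec, f) for f in spec.__dataclass_fields__})


def load_model(path) -> Network:
    with np.load(path, allow_pickle=False) as arc:
        fields = {f: int(arc[f"spec_{f}"])
                  for f in ArchitectureSpec.__dataclass_fields__}
        spec = ArchitectureSpec(**fields)
        net = build_architecture(spec, seed=0)
        net.load_state_arrays({k: arc[k] for k in arc.files
                               if k.startswith("param_")})
    return net
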