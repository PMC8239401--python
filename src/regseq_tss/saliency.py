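"""Gradient saliency maps for trained sequence classifiers.

The importance of each nucleotide is taken from the first-order Taylor
expansion of the class score around the input: the score S(X) of the
promoter class is locally approximated by w^T X + b, where w is the gradient
of the pre-sigmoid score with respect to the one-hot input, obtained by a
single backward pass. The raw per-position score is the absolute gradient at
the observed channel; scores are normalized to sum to one within each
sequence, and a position is called important when its normalized score
strictly exceeds the uniform level 1/l (0.002 for 500-bp windows, 1/600 for
600-bp windows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import Network
from .sequence_io import EncodedSequence, stack_onehot
from .cnn_model import predict

logger = logging.getLogger(__name__)


@dataclass
class SaliencyResult:
    """Per-position importance for one sequence."""

    sequence_id: str
    raw_scores: np.ndarray
    normalized_scores: np.ndarray

    @property
    def length(self) -> int:
        return len(self.normalized_scores)

    @property
    def threshold(self) -> float:
        return 1.0 / self.length

    @property
    def important_positions(self) -> np.ndarray:
        return np.flatnonzero(self.normalized_scores > self.threshold)


@dataclass
class AggregateMap:
    """Row-stacked normalized saliency over midpoint-relative positions."""

    matrix: np.ndarray  # (n_sequences, l)
    sequence_ids: list[str]

    @property
    def positions(self) -> np.ndarray:
        l = self.matrix.shape[1]
        return np.arange(-l // 2, l - l // 2)

    def region_mean(self, start: int, end: int) -> float:
        """Mean normalized score over the midpoint-relative slice [start, end)."""
        l = self.matrix.shape[1]
        lo, hi = start + l // 2, end + l // 2
        if lo < 0 or hi > l or lo >= hi:
            raise ValueError(f"slice [{start}, {end}) outside [-{l//2}, {l - l//2})")
        return float(self.matrix[:, lo:hi].mean())

    def per_sequence_region_mean(self, start: int, end: int) -> np.ndarray:
        l = self.matrix.shape[1]
        lo, hi = start + l // 2, end + l // 2
        if lo < 0 or hi > l or lo >= hi:
            raise ValueError(f"slice [{start}, {end}) outside [-{l//2}, {l - l//2})")
        return self.matrix[:, lo:hi].mean(axis=1)


def compute_saliency_batch(model: Network, sequences: Sequence[EncodedSequence],
                           reduce: str = "observed") -> list[SaliencyResult]:
    """Saliency for a batch of same-length sequences (single backward pass).

    ``reduce`` selects the channel-reduction rule: ``"observed"`` (default)
    takes |gradient| at the observed channel; ``"max"`` takes the maximum
    |gradient| over the four channels.
    """
    x = stack_onehot(sequences)
    grad = model.input_gradient(x)  # (B, l, 4)
    if reduce == "observed":
        raw = np.abs((grad * x).sum(axis=2))
    elif reduce == "max":
        raw = np.abs(grad).max(axis=2)
    else:
        raise ValueError(f"unknown channel reduction {reduce!r}")
    return [
        SaliencyResult(
            sequence_id=s.id,
            raw_scores=raw[i].astype(np.float64),
            normalized_scores=normalize_scores(raw[i].astype(np.float64)),
        )
        for i, s in enumerate(sequences)
    ]


def compute_saliency(model: Network, seq: EncodedSequence,
                     reduce: str = "observed") -> SaliencyResult:
    """Saliency scores for one sequence (promoter-class score gradient)."""
    return compute_saliency_batch(model, [seq], reduce=reduce)[0]


def normalize_scores(raw: np.ndarray) -> np.ndarray:
    """Divide by the per-sequence sum; all-zero input yields the uniform 1/l."""
    raw = np.asarray(raw, dtype=np.float64)
    if np.any(raw < 0):
        raise ValueError("raw saliency scores must be non-negative")
    total = raw.sum()
    if total == 0.0:
        return np.full(raw.shape, 1.0 / raw.size)
    return raw / total


def call_important_positions(normalized: np.ndarray, l: int | None = None
                             ) -> np.ndarray:
    """Positions whose normalized score strictly exceeds 1/l."""
    normalized = np.asarray(normalized)
    if l is None:
        l = normalized.size
    return np.flatnonzero(normalized > 1.0 / l)


def select_top_predictions(model: Network, sequences: Sequence[EncodedSequence],
                           prob_min: float = 0.95, top_n: int = 50
                           ) -> list[EncodedSequence]:
    """The top-n sequences predicted promoter with probability > prob_min.

    Sorted by descending probability (ties broken by input order); returns
    fewer than ``top_n`` if fewer qualify.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    probs = predict(model, sequences)
    qualifying = np.flatnonzero(probs > prob_min)
    if qualifying.size == 0:
        logger.warning("no sequence predicted above %.2f", prob_min)
        return []
    order = qualifying[np.argsort(-probs[qualifying], kind="stable")][:top_n]
    if qualifying.size < top_n:
        logger.info("only %d sequences above %.2f (requested %d)",
                    qualifying.size, prob_min, top_n)
    return [sequences[i] for i in order]


def aggregate_saliency(results: Sequence[SaliencyResult]) -> AggregateMap:
    """Stack normalized scores into a (n, l) midpoint-relative map."""
    lengths = {r.length for r in results}
    if len(lengths) != 1:
        raise ValueError(f"mixed saliency lengths: {sorted(lengths)}")
    return AggregateMap(
        matrix=np.stack([r.normalized_scores for r in results]),
        sequence_ids=[r.sequence_id for r in results],
    )
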