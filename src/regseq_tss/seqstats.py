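"""GC-content characterization of TSS windows.

GC content is (G+C)/(A+T+G+C): uncalled bases (N) count in neither the
numerator nor the denominator. Reports cover whole windows, midpoint-relative
slices (e.g. the +20..+120 bp downstream region), and the positions a
saliency map calls important. For important positions the group value is
pooled — total G+C over total counted bases across sequences — because the
per-sequence important sets vary in size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .saliency import SaliencyResult
from .sequence_io import EncodedSequence

_GC = frozenset("GC")
_ACGT = frozenset("ACGT")


@dataclass
class GCReport:
    """Per-sequence GC fractions and their group summary.

    ``per_sequence`` entries are NaN where a sequence had no counted bases
    in the selected positions. ``pooled`` is the count-weighted group value
    (used for important-position GC); ``mean`` is the arithmetic mean of the
    defined per-sequence fractions. Both are None when nothing was counted.
    """

    per_sequence: np.ndarray
    gc_bases: int
    counted_bases: int
    region: tuple[int, int] | None = None

    @property
    def mean(self) -> float | None:
        defined = self.per_sequence[~np.isnan(self.per_sequence)]
        return float(defined.mean()) if defined.size else None

    @property
    def pooled(self) -> float | None:
        return self.gc_bases / self.counted_bases if self.counted_bases else None


def _gc_counts(seq: str, positions=None) -> tuple[int, int]:
    chars = seq if positions is None else (seq[p] for p in positions)
    gc = counted = 0
    for ch in chars:
        if ch in _GC:
            gc += 1
            counted += 1
        elif ch in _ACGT:
            counted += 1
    return gc, counted


def gc_content(seq: str | EncodedSequence, positions=None) -> float | None:
    """(G+C)/(A+T+G+C) over ``positions`` (default: all); None if no base
    in the effective set is called."""
    s = seq.sequence if isinstance(seq, EncodedSequence) else seq.upper()
    gc, counted = _gc_counts(s, positions)
    return gc / counted if counted else None


def regional_gc(sequences: Sequence[EncodedSequence],
                region: tuple[int, int] | None = None) -> GCReport:
    """GC over a midpoint-relative half-open slice ``[start, end)``.

    ``region=None`` means the whole window. The +20..+120 downstream region
    of the sense TSS is ``(20, 120)``.
    """
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths: {sorted(lengths)}")
    l = lengths.pop()
    if region is None:
        lo, hi = 0, l
    else:
        lo, hi = region[0] + l // 2, region[1] + l // 2
        if lo < 0 or hi > l or lo >= hi:
            raise ValueError(
                f"region {region} outside the window [-{l//2}, {l - l//2})"
            )
    fracs, gc_total, counted_total = [], 0, 0
    for s in sequences:
        gc, counted = _gc_counts(s.sequence[lo:hi])
        fracs.append(gc / counted if counted else np.nan)
        gc_total += gc
        counted_total += counted
    return GCReport(per_sequence=np.asarray(fracs), gc_bases=gc_total,
                    counted_bases=counted_total, region=region)


def gc_at_important_positions(sequences: Sequence[EncodedSequence],
                              saliency_results: Sequence[SaliencyResult]
                              ) -> GCReport:
    """GC pooled over each sequence's saliency-called important positions."""
    if len(sequences) != len(saliency_results):
        raise ValueError("sequences and saliency results must pair up")
    fracs, gc_total, counted_total = [], 0, 0
    for s, r in zip(sequences, saliency_results):
        if len(s) != r.length:
            raise ValueError(
                f"sequence {s.id!r}: length {len(s)} != saliency length {r.length}"
            )
        gc, counted = _gc_counts(s.sequence, r.important_positions)
        fracs.append(gc / counted if counted else np.nan)
        gc_total += gc
        counted_total += counted
    return GCReport(per_sequence=np.asarray(fracs), gc_bases=gc_total,
                    counted_bases=counted_total)
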