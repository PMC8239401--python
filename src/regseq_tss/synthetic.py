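"""Synthetic bidirectional-TSS window generator.

Emulates the sequence-level structure that separates promoter-like
(unstable-stable, US) from enhancer-like (unstable-unstable, UU) TSS pairs:
class-dependent overall GC composition (defaults 63% vs 50%) with an
additionally GC-elevated +20..+120 bp region downstream of the sense TSS
(defaults 67% vs 51%), the empirical mean spacing between the divergent
TSSs (120 bp vs 91 bp, as metadata), and optional planted consensus motifs.

Each position is drawn independently; G/C and A/T split their totals evenly.
Positions outside the downstream region use a flank GC level solved so that
the whole-window expectation equals the global parameter. The generator is a
pure function of its seed: identical spec and seed give byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import (
    ENHANCER,
    PROMOTER,
    EncodedSequence,
    write_fasta,
    write_label_tsv,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MotifPlant:
    """A consensus string planted uniformly at random inside a window.

    ``window`` is midpoint-relative and half-open; ``prob_promoter`` /
    ``prob_enhancer`` are the per-sequence plant probabilities by class.
    """

    consensus: str
    window: tuple[int, int]
    prob_promoter: float = 1.0
    prob_enhancer: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one labeled dataset."""

    n_promoter: int = 1000
    n_enhancer: int = 1000
    length: int = 500
    promoter_gc_global: float = 0.63
    enhancer_gc_global: float = 0.50
    promoter_gc_downstream: float = 0.67
    enhancer_gc_downstream: float = 0.51
    downstream_region: tuple[int, int] = (20, 120)
    promoter_spacing_mean: float = 120.0
    enhancer_spacing_mean: float = 91.0
    spacing_sd: float = 30.0
    motifs: tuple[MotifPlant, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_promoter < 1 or self.n_enhancer < 1:
            raise ValueError("class counts must be >= 1")
        if self.length % 100:
            raise ValueError("length must be divisible by 100")
        for name in ("promoter_gc_global", "enhancer_gc_global",
                     "promoter_gc_downstream", "enhancer_gc_downstream"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for gc_global, gc_down in ((self.promoter_gc_global,
                                    self.promoter_gc_downstream),
                                   (self.enhancer_gc_global,
                                    self.enhancer_gc_downstream)):
            self._flank_gc(gc_global, gc_down)

    def _flank_gc(self, gc_global: float, gc_down: float) -> float:
        """GC of positions outside the downstream region such that the
        whole-window expectation equals ``gc_global``."""
        lo, hi = self.downstream_region
        width = hi - lo
        flank = (gc_global * self.length - gc_down * width) / (self.length - width)
        if not 0.0 < flank < 1.0:
            raise ValueError(
                f"infeasible GC parameters: global {gc_global} with "
                f"downstream {gc_down} over {width} bp requires flank GC "
                f"{flank:.4f}, outside (0, 1)"
            )
        return flank


@dataclass
class SyntheticDataset:
    """Generated sequences plus per-sequence metadata."""

    sequences: list[EncodedSequence]
    metadata: pd.DataFrame
    spec: SyntheticSpec

    def write(self, outdir: str | Path, contig: str = "synth1") -> dict[str, Path]:
        """Write FASTA, BED midpoints and a label TSV; windows tile the
        synthetic contig end to end."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "sequences.fa",
            "bed": outdir / "midpoints.bed",
            "labels": outdir / "labels.tsv",
            "metadata": outdir / "metadata.tsv",
        }
        write_fasta(self.sequences, paths["fasta"])
        write_label_tsv(self.sequences, paths["labels"])
        l = self.spec.length
        with open(paths["bed"], "w") as fh:
            for i, s in enumerate(self.sequences):
                mid = i * l + l // 2
                fh.write(f"{contig}\t{mid}\t{mid + 1}\t{s.id}\n")
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        return paths


def _draw_background(rng: np.random.Generator, n: int, gc_per_pos: np.ndarray
                     ) -> np.ndarray:
    """Draw an (n, l) uint8 base matrix with per-position GC probability.

    With P(A)=P(T)=(1-gc)/2 and P(C)=P(G)=gc/2 the cumulative cutpoints are
    (1-gc)/2, 1/2 and (1+gc)/2 for A|C, C|G and G|T respectively.
    """
    u = rng.random((n, gc_per_pos.size))
    idx = ((u >= (1.0 - gc_per_pos) / 2.0).astype(np.uint8)
           + (u >= 0.5)
           + (u >= (1.0 + gc_per_pos) / 2.0))
    return _BASES[idx]


def plant_motif(sequence: str, motif: str, window: tuple[int, int],
                rng: np.random.Generator) -> tuple[str, int | None]:
    """Overwrite the background with ``motif`` at a uniform offset in the
    half-open 0-based ``window``; returns (sequence, start) with start None
    for an empty motif."""
    if not motif:
        return sequence, None
    lo, hi = window
    if hi - lo < len(motif):
        raise ValueError(
            f"motif of length {len(motif)} does not fit window [{lo}, {hi})"
        )
    if lo < 0 or hi > len(sequence):
        raise ValueError(f"window [{lo}, {hi}) outside sequence")
    start = int(rng.integers(lo, hi - len(motif) + 1))
    return sequence[:start] + motif.upper() + sequence[start + len(motif):], start


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the labeled dataset described by ``spec``.

    Promoter-class sequences come first, then enhancer-class; metadata
    records the TSS spacing draw and any planted motif positions.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    l = spec.length
    lo, hi = spec.downstream_region
    down_slice = slice(lo + l // 2, hi + l // 2)

    sequences: list[EncodedSequence] = []
    rows: list[dict] = []
    class_plan = (
        ("prom", PROMOTER, spec.n_promoter, spec.promoter_gc_global,
         spec.promoter_gc_downstream, spec.promoter_spacing_mean),
        ("enh", ENHANCER, spec.n_enhancer, spec.enhancer_gc_global,
         spec.enhancer_gc_downstream, spec.enhancer_spacing_mean),
    )
    for prefix, label, n, gc_global, gc_down, spacing_mean in class_plan:
        gc_per_pos = np.full(l, spec._flank_gc(gc_global, gc_down))
        gc_per_pos[down_slice] = gc_down
        mat = _draw_background(rng, n, gc_per_pos)
        spacing = np.clip(
            np.round(rng.normal(spacing_mean, spec.spacing_sd, size=n)),
            10, 400,
        ).astype(int)
        for i in range(n):
            seq = mat[i].tobytes().decode("ascii")
            planted: dict[str, int | None] = {}
            for m in spec.motifs:
                prob = m.prob_promoter if label == PROMOTER else m.prob_enhancer
                if rng.random() < prob:
                    win = (m.window[0] + l // 2, m.window[1] + l // 2)
                    seq, start = plant_motif(seq, m.consensus, win, rng)
                    planted[m.consensus] = None if start is None else start - l // 2
            sid = f"{prefix}_{i:05d}"
            sequences.append(EncodedSequence(id=sid, sequence=seq, label=label))
            rows.append({
                "id": sid, "label": label, "tss_spacing": int(spacing[i]),
                "sense_tss": int(spacing[i]) // 2,
                **{f"motif_{k}": v for k, v in planted.items()},
            })
    return SyntheticDataset(sequences=sequences,
                            metadata=pd.DataFrame(rows), spec=spec)
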