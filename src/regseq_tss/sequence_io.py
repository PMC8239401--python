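"""Sequence and interval I/O for bidirectional-TSS windows.

Reads fixed-length DNA windows centered on the midpoint between a pair of
divergent transcription start sites, together with their promoter/enhancer
labels, and converts them to the 4-channel one-hot representation the
convolutional models consume.

Conventions
-----------
* Coordinates are BED-style: 0-based, half-open. A window around ``midpoint``
  with flank ``f`` is ``[midpoint - f, midpoint + f)`` and has length ``2*f``.
* One-hot channel order is (A, C, G, T); ``N`` encodes as an all-zero row.
* Windows are oriented so the sense (stable) TSS points in the +x direction;
  positions downstream of the midpoint therefore have positive
  midpoint-relative coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

#: Channel order of the one-hot encoding.
ALPHABET = "ACGT"

_CHANNEL_INDEX = {b: i for i, b in enumerate(ALPHABET)}

PROMOTER, ENHANCER = 1, 0


@dataclass(frozen=True)
class GenomicWindow:
    """Fixed-length interval centered on a bidirectional-TSS midpoint."""

    chrom: str
    midpoint: int
    flank: int

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ValueError(f"flank must be positive, got {self.flank}")

    @property
    def start(self) -> int:
        return self.midpoint - self.flank

    @property
    def end(self) -> int:
        return self.midpoint + self.flank

    @property
    def length(self) -> int:
        return 2 * self.flank


@dataclass
class EncodedSequence:
    """A labeled DNA window plus its one-hot matrix.

    ``label`` is 1 for the promoter class (unstable-stable TSS pair) and 0
    for the enhancer class (unstable-unstable pair). ``relative_coords``
    run from ``-l/2`` to ``l/2 - 1`` relative to the TSS midpoint.
    """

    id: str
    sequence: str
    label: int | None = None
    onehot: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    window: GenomicWindow | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.onehot is None:
            self.onehot = one_hot_encode(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def relative_coords(self) -> np.ndarray:
        l = len(self.sequence)
        return np.arange(-l // 2, l - l // 2)


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as an ``l x 4`` matrix, channels (A, C, G, T).

    ``N`` becomes an all-zero row so that every row sums to 1 for a called
    base and 0 for a missing one. Any other character is an error.
    """
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    onehot = np.zeros((len(seq), 4), dtype=np.float32)
    for base, channel in _CHANNEL_INDEX.items():
        onehot[arr == ord(base), channel] = 1.0
    known = onehot.sum(axis=1) + (arr == ord("N"))
    if not np.all(known == 1):
        pos = int(np.argmin(known))
        raise ValueError(
            f"invalid character {seq[pos]!r} at position {pos}; "
            "alphabet is A/C/G/T/N"
        )
    return onehot


def decode_one_hot(onehot: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` for N-free matrices (argmax per row)."""
    return "".join(ALPHABET[i] for i in np.asarray(onehot).argmax(axis=1))


def read_label_tsv(path: str | Path) -> dict[str, int]:
    """Read a two-column, headerless, tab-separated id -> label file."""
    labels: dict[str, int] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
        labels[fields[0]] = int(fields[1])
    return labels


def read_labeled_fasta(
    path: str | Path, label_map: Mapping[str, int]
) -> list[EncodedSequence]:
    """Read same-length FASTA records and attach labels.

    Every record id must appear in ``label_map``; record order is preserved
    and sequences are upper-cased. A length mismatch among records is fatal.
    """
    out: list[EncodedSequence] = []
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in label_map:
            raise KeyError(f"no label for sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"record {rec.id!r} has length {len(seq)}, expected {length}"
            )
        out.append(EncodedSequence(id=rec.id, sequence=seq, label=label_map[rec.id]))
    return out


def read_midpoint_bed(path: str | Path) -> list[tuple[str, int]]:
    """Read BED records and reduce each to (chrom, midpoint).

    A 1-bp record's single base is the midpoint; wider records use the
    interval center (floor of the mean of start and end).
    """
    midpoints: list[tuple[str, int]] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{line_no}: BED needs >=3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        midpoints.append((chrom, (start + end) // 2))
    return midpoints


def extract_windows(
    midpoints: Iterable[tuple[str, int]] | str | Path,
    genome: str | Path | Fasta,
    flank: int,
) -> list[EncodedSequence]:
    """Extract ``2*flank``-bp windows centered on TSS midpoints.

    ``midpoints`` may be a BED path or an iterable of (chrom, midpoint).
    Windows overrunning a contig boundary are dropped and logged; a contig
    absent from the genome is fatal.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if isinstance(midpoints, (str, Path)):
        midpoints = read_midpoint_bed(midpoints)
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    out: list[EncodedSequence] = []
    for i, (chrom, midpoint) in enumerate(midpoints):
        if chrom not in fa:
            raise KeyError(f"contig {chrom!r} not present in genome")
        win = GenomicWindow(chrom=chrom, midpoint=midpoint, flank=flank)
        contig_len = len(fa[chrom])
        if win.start < 0 or win.end > contig_len:
            logger.warning(
                "dropping window %s:%d-%d (contig length %d)",
                chrom, win.start, win.end, contig_len,
            )
            continue
        seq = str(fa[chrom][win.start : win.end]).upper()
        out.append(
            EncodedSequence(
                id=f"{chrom}:{win.start}-{win.end}", sequence=seq, window=win
            )
        )
    return out


def write_fasta(sequences: Sequence[EncodedSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n{s.sequence}\n")


def write_label_tsv(sequences: Sequence[EncodedSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f"{s.id}\t{s.label}\n")


def stack_onehot(sequences: Sequence[EncodedSequence]) -> np.ndarray:
    """Stack one-hot matrices into a (n, l, 4) batch array."""
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValueError(f"mixed sequence lengths: {sorted(lengths)}")
    return np.stack([s.onehot for s in sequences])


def labels_of(sequences: Sequence[EncodedSequence]) -> np.ndarray:
    labels = [s.label for s in sequences]
    if any(lab is None for lab in labels):
        raise ValueError("unlabeled sequence in labeled batch")
    return np.asarray(labels, dtype=np.int64)
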