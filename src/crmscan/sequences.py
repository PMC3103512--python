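"""Genome sequence handling with scan masks.

Sequences are held upper-case; repeat masking (lower-case letters in
soft-masked FASTA) and coding-region masking (CDS features from a gene
annotation) are merged into a single boolean mask so that downstream
binding-site scanning only sees non-coding, non-repetitive positions.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; any other letter (N, ambiguity) as 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for base, code in _CODES.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class SequenceRecord:
    """A named DNA sequence plus intervals excluded from scanning."""

    seq_id: str
    sequence: str
    mask: np.ndarray = field(default=None)  # bool, True = masked

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(len(self.sequence), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.sequence),):
            raise ValueError("mask length must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    def add_masked_interval(self, start: int, end: int) -> None:
        if start < 0 or end > len(self) or start > end:
            raise ValueError(
                f"masked interval [{start}, {end}) outside sequence "
                f"{self.seq_id!r} of length {len(self)}"
            )
        self.mask[start:end] = True

    @property
    def masked_intervals(self) -> list[tuple[int, int]]:
        """Maximal masked runs as a sorted list of (start, end)."""
        if not self.mask.any():
            return []
        padded = np.concatenate([[False], self.mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        return list(zip(edges[::2].tolist(), edges[1::2].tolist()))

    @classmethod
    def from_seq(cls, seq_id: str, sequence: str,
                 mask_lowercase: bool = True) -> "SequenceRecord":
        mask = np.zeros(len(sequence), dtype=bool)
        if mask_lowercase:
            arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
            mask = (arr >= ord("a")) & (arr <= ord("z"))
        return cls(seq_id, sequence.upper(), mask)


def read_fasta(path: str | Path, mask_lowercase: bool = True
               ) -> dict[str, SequenceRecord]:
    """Read a (soft-masked) FASTA file into SequenceRecords keyed by id."""
    records: dict[str, SequenceRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = SequenceRecord.from_seq(
            rec.id, str(rec.seq), mask_lowercase=mask_lowercase)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                soft_mask: bool = True, width: int = 70) -> None:
    """Write records, lower-casing masked positions when soft_mask."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.sequence
            if soft_mask and rec.mask.any():
                chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                chars[rec.mask] += 32  # to lower case
                seq = chars.tobytes().decode("ascii")
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def iter_windows(record: SequenceRecord, width: int) -> Iterator[int]:
    """Start positions of unmasked, N-free windows (a brute-force helper)."""
    codes = encode(record.sequence)
    for start in range(len(record) - width + 1):
        window = slice(start, start + width)
        if record.mask[window].any() or (codes[window] == 4).any():
            continue
        yield start
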