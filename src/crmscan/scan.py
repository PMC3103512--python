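"""Genome scanning for binding-site hits.

Both strands are scored at every unmasked, N-free window; the reverse
strand is handled by scoring the forward window against the
reverse-complemented matrix, which equals scoring the reverse complement
of the window against the matrix itself.  The per-matrix hit threshold is
a fraction of the maximum achievable bit score (default 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .pwm import PWM
from .sequences import SequenceRecord, encode


@dataclass(frozen=True)
class BindingSiteHit:
    """One PWM match on a genome sequence (0-based, half-open)."""

    matrix_id: str
    seq_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    score: float  # log-odds bits

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def hit_threshold(pwm: PWM, fraction: float = 0.75) -> float:
    """Per-matrix score cutoff: ``fraction`` of the maximum bit score."""
    return fraction * pwm.max_score()


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every window start; windows containing non-ACGT get -inf."""
    w = lo.shape[0]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0)
    # pad the log-odds table with a -inf column for code 4 (N/ambiguous)
    padded = np.hstack([lo, np.full((w, 1), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return padded[np.arange(w), windows].sum(axis=1)


def scan(record: SequenceRecord, pwm: PWM,
         threshold_fraction: float = 0.75,
         threshold: float | None = None) -> list[BindingSiteHit]:
    """Scan one sequence with one matrix on both strands.

    A window overlapping a masked position or containing a non-ACGT letter
    is skipped.  ``threshold`` overrides the fractional policy when given.
    """
    w = pwm.width
    if len(record) < w:
        return []
    cutoff = hit_threshold(pwm, threshold_fraction) if threshold is None else threshold
    codes = encode(record.sequence)
    n = len(record) - w + 1
    # window is valid iff no masked base inside it
    masked_any = np.convolve(record.mask.astype(np.int32), np.ones(w, dtype=np.int32),
                             mode="valid") > 0
    hits: list[BindingSiteHit] = []
    for strand, table in (("+", pwm.log_odds()),
                          ("-", pwm.reverse_complement().log_odds())):
        scores = _window_scores(codes, table)
        ok = (scores >= cutoff) & ~masked_any[:n]
        for pos in np.flatnonzero(ok):
            hits.append(BindingSiteHit(pwm.matrix_id, record.seq_id,
                                       int(pos), int(pos) + w, strand,
                                       float(scores[pos])))
    hits.sort(key=lambda h: (h.start, h.strand, h.matrix_id))
    return hits


def scan_all(records: Iterable[SequenceRecord], pwms: Iterable[PWM],
             threshold_fraction: float = 0.75) -> list[BindingSiteHit]:
    """Scan every record with every matrix; hits sorted per sequence."""
    hits: list[BindingSiteHit] = []
    pwms = list(pwms)
    for record in records:
        for pwm in pwms:
            hits.extend(scan(record, pwm, threshold_fraction=threshold_fraction))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand, h.matrix_id))
    return hits


def write_hits_bed(hits: Sequence[BindingSiteHit], path: str | Path) -> None:
    """BED6: name = matrix id, score = bits x 100 rounded."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.matrix_id}\t"
                     f"{round(h.score * 100)}\t{h.strand}\n")


def read_hits_bed(path: str | Path) -> list[BindingSiteHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            seq_id, start, end, name, score, strand = line.split("\t")[:6]
            hits.append(BindingSiteHit(name, seq_id, int(start), int(end),
                                       strand.strip(), int(score) / 100.0))
    return hits
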