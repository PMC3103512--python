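"""Cross-species support for binding-site hits.

A reference-genome hit is projected through pairwise alignment blocks into
each comparison genome, the projected neighbourhood (+/- 20 bp, allowing
slightly misaligned sites) is rescanned with the same matrix, and the best
supporting hit feeds the combined score

    combined = ref_score + max_species( max(0, species_score - lam * |offset|) )

so a site scores high either through strong reference binding alone or
through conservation in at least one comparison species.  Misalignment is
penalized linearly (``lam`` bits/bp, default 0.1) and floored at zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pwm import PWM
from .scan import BindingSiteHit, hit_threshold, scan
from .sequences import SequenceRecord

MAX_OFFSET = 20  # bp of tolerated misalignment
DEFAULT_LAMBDA = 0.1  # bits of penalty per bp of misalignment
SPECIES_ORDER = ("tetraodon", "stickleback", "fugu")


@dataclass
class AlignmentBlock:
    """One gapped pairwise alignment block, reference vs one species.

    ``ref_to_other[i]`` is the comparison-genome position aligned to
    reference position ``ref_start + i``, or -1 where the reference base
    falls in a gap.  The map must be monotone non-decreasing over its
    non-gap entries.
    """

    ref_seq_id: str
    ref_start: int
    ref_end: int
    species: str
    other_seq_id: str
    other_start: int
    other_end: int
    ref_to_other: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ref_to_other = np.asarray(self.ref_to_other, dtype=np.int64)
        if self.ref_to_other.shape != (self.ref_end - self.ref_start,):
            raise ValueError("offset map length must equal reference span")
        mapped = self.ref_to_other[self.ref_to_other >= 0]
        if mapped.size and (np.diff(mapped) < 0).any():
            raise ValueError("offset map must be monotone non-decreasing")
        if mapped.size and (mapped.min() < self.other_start
                            or mapped.max() >= self.other_end):
            raise ValueError("offset map escapes the comparison interval")

    @classmethod
    def from_cigar(cls, ref_seq_id: str, ref_start: int, species: str,
                   other_seq_id: str, other_start: int, cigar: str
                   ) -> "AlignmentBlock":
        """Build from a cigar-like gap string.

        Ops: ``M`` advance both genomes, ``D`` advance the reference only
        (gap in the comparison genome), ``I`` advance the comparison only.
        """
        ref_map: list[int] = []
        rpos, opos = ref_start, other_start
        for num, op in re.findall(r"(\d+)([MDI])", cigar):
            n = int(num)
            if op == "M":
                ref_map.extend(range(opos, opos + n))
                rpos += n
                opos += n
            elif op == "D":
                ref_map.extend([-1] * n)
                rpos += n
            else:  # I
                opos += n
        if not re.fullmatch(r"(?:\d+[MDI])+", cigar):
            raise ValueError(f"malformed cigar string {cigar!r}")
        return cls(ref_seq_id, ref_start, rpos, species, other_seq_id,
                   other_start, opos, np.array(ref_map, dtype=np.int64))


def read_block_table(path: str | Path) -> list[AlignmentBlock]:
    """TSV dialect: ref_seq ref_start ref_end species other_seq other_start other_end cigar."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            (ref_seq, ref_start, ref_end, species,
             other_seq, other_start, other_end, cigar) = line.rstrip("\n").split("\t")
            block = AlignmentBlock.from_cigar(ref_seq, int(ref_start), species,
                                              other_seq, int(other_start), cigar)
            if block.ref_end != int(ref_end) or block.other_end != int(other_end):
                raise ValueError(
                    f"block ends {block.ref_end}/{block.other_end} disagree with "
                    f"table entry {ref_end}/{other_end}")
            blocks.append(block)
    return blocks


def write_block_table(blocks: Sequence[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#ref_seq\tref_start\tref_end\tspecies\tother_seq\t"
                 "other_start\tother_end\tcigar\n")
        for b in blocks:
            fh.write("\t".join([b.ref_seq_id, str(b.ref_start), str(b.ref_end),
                                b.species, b.other_seq_id, str(b.other_start),
                                str(b.other_end), _to_cigar(b)]) + "\n")


def _to_cigar(block: AlignmentBlock) -> str:
    """Reconstruct the gap string from the offset map (inverse of from_cigar)."""
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    opos = block.other_start
    for val in block.ref_to_other:
        if val < 0:
            push("D", 1)
        else:
            push("I", int(val) - opos)
            push("M", 1)
            opos = int(val) + 1
    push("I", block.other_end - opos)
    return "".join(f"{n}{op}" for op, n in ops)


def read_maf(path: str | Path, ref_prefix: str | None = None
             ) -> list[AlignmentBlock]:
    """Read pairwise blocks from a MAF file.

    The first ``s`` row of each block is the reference; every further row
    yields one block against that row's species.  Sequence names follow the
    MAF convention ``species.seq_id``.  Only forward-strand comparison rows
    are accepted: the offset map is required to be monotone non-decreasing,
    which a reverse-strand row cannot satisfy.
    """
    from Bio import AlignIO

    blocks: list[AlignmentBlock] = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows = list(aln)
        if len(rows) < 2:
            continue
        ref = rows[0]
        ref_sp, _, ref_seq_id = ref.id.partition(".")
        if ref_prefix is not None and ref_sp != ref_prefix:
            raise ValueError(f"first MAF row is {ref_sp!r}, expected {ref_prefix!r}")
        ref_text = str(ref.seq).upper()
        ref_start = ref.annotations["start"]
        for row in rows[1:]:
            species, _, other_seq_id = row.id.partition(".")
            other_text = str(row.seq).upper()
            strand = row.annotations.get("strand", 1)
            if strand != 1:
                raise ValueError(
                    f"reverse-strand MAF row for {row.id}: not representable "
                    "as a monotone reference-to-comparison offset map")
            start = row.annotations["start"]
            size = row.annotations["size"]
            ref_map: list[int] = []
            rpos, opos = ref_start, 0  # opos counts comparison bases consumed
            for rc, oc in zip(ref_text, other_text):
                if rc != "-" and oc != "-":
                    ref_map.append(start + opos)
                    rpos += 1
                    opos += 1
                elif rc != "-":
                    ref_map.append(-1)
                    rpos += 1
                elif oc != "-":
                    opos += 1
            blocks.append(AlignmentBlock(
                ref_seq_id, ref_start, rpos, species, other_seq_id,
                start, start + size, np.array(ref_map, dtype=np.int64)))
    return blocks


def sort_and_check(blocks: Sequence[AlignmentBlock]) -> list[AlignmentBlock]:
    """Sort blocks by reference interval and reject overlaps (per species)."""
    out = sorted(blocks, key=lambda b: (b.species, b.ref_seq_id, b.ref_start))
    for a, b in zip(out, out[1:]):
        if (a.species == b.species and a.ref_seq_id == b.ref_seq_id
                and b.ref_start < a.ref_end):
            raise ValueError(
                f"overlapping alignment blocks on {a.ref_seq_id} "
                f"({a.ref_start}-{a.ref_end} vs {b.ref_start}-{b.ref_end})")
    return out


def map_hit(hit: BindingSiteHit, blocks: Sequence[AlignmentBlock],
            species: str, max_offset: int = MAX_OFFSET
            ) -> tuple[str, int, int, int, int] | None:
    """Project a reference hit into a comparison genome.

    Returns ``(other_seq_id, proj_start, proj_end, win_start, win_end)``
    where the window is the projection widened by ``max_offset`` on each
    side and clipped to the block, or ``None`` when the hit lies outside
    every block of that species.
    """
    for block in blocks:
        if (block.species != species or block.ref_seq_id != hit.seq_id
                or hit.start < block.ref_start or hit.end > block.ref_end):
            continue
        lo = hit.start - block.ref_start
        mapped = block.ref_to_other[lo:lo + (hit.end - hit.start)]
        mapped = mapped[mapped >= 0]
        if mapped.size == 0:
            return None  # hit falls entirely in a gap
        proj_start, proj_end = int(mapped.min()), int(mapped.max()) + 1
        win_start = max(block.other_start, proj_start - max_offset)
        win_end = min(block.other_end, proj_end + max_offset)
        return block.other_seq_id, proj_start, proj_end, win_start, win_end
    return None


@dataclass(frozen=True)
class SpeciesSupport:
    """Best same-matrix hit near the projected site in one species."""

    species: str
    score: float  # bits
    offset: int  # bp between the supporting hit and the projection

    def __post_init__(self) -> None:
        if abs(self.offset) > MAX_OFFSET:
            raise ValueError(f"offset {self.offset} exceeds {MAX_OFFSET} bp")


@dataclass(frozen=True)
class ConservedHit:
    """A reference hit with its conservation-weighted combined score."""

    ref_hit: BindingSiteHit
    support: tuple[SpeciesSupport, ...]
    combined_score: float
    supporting_species: str | None = None

    @property
    def seq_id(self) -> str:
        return self.ref_hit.seq_id

    @property
    def start(self) -> int:
        return self.ref_hit.start

    @property
    def end(self) -> int:
        return self.ref_hit.end

    @property
    def matrix_id(self) -> str:
        return self.ref_hit.matrix_id


def combine(hit: BindingSiteHit,
            species_hits: Mapping[str, tuple[float, int] | None],
            lam: float = DEFAULT_LAMBDA) -> ConservedHit:
    """Fold per-species support into the combined score.

    ``species_hits`` maps species name to ``(score_bits, offset_bp)`` or
    ``None`` when no supporting hit was found; absent species contribute
    nothing, so an unsupported hit keeps its reference score.
    """
    support: list[SpeciesSupport] = []
    best = 0.0
    best_species: str | None = None
    order = [s for s in SPECIES_ORDER if s in species_hits]
    order += [s for s in species_hits if s not in SPECIES_ORDER]
    for species in order:
        entry = species_hits[species]
        if entry is None:
            continue
        score, offset = entry
        sup = SpeciesSupport(species, float(score), int(offset))  # validates offset
        support.append(sup)
        penalized = max(0.0, sup.score - lam * abs(sup.offset))
        if penalized > best:
            best = penalized
            best_species = species
    return ConservedHit(hit, tuple(support), hit.score + best, best_species)


def find_support(hit: BindingSiteHit, pwm: PWM,
                 blocks: Sequence[AlignmentBlock],
                 species_records: Mapping[str, Mapping[str, SequenceRecord]],
                 threshold_fraction: float = 0.75,
                 max_offset: int = MAX_OFFSET
                 ) -> dict[str, tuple[float, int] | None]:
    """Rescan each comparison genome around the projected hit.

    Returns, per species, the best same-matrix hit (either strand) within
    the misalignment window as ``(score, offset)``; ``None`` when the hit
    does not project or nothing scores above the matrix threshold.
    """
    cutoff = hit_threshold(pwm, threshold_fraction)
    out: dict[str, tuple[float, int] | None] = {}
    for species, seqs in species_records.items():
        projection = map_hit(hit, blocks, species, max_offset=max_offset)
        out[species] = None
        if projection is None:
            continue
        other_seq_id, proj_start, _, win_start, win_end = projection
        record = seqs.get(other_seq_id)
        if record is None or win_end - win_start < pwm.width:
            continue
        window = SequenceRecord(record.seq_id,
                                record.sequence[win_start:win_end])
        best: tuple[float, int] | None = None
        for cand in scan(window, pwm, threshold=cutoff):
            offset = (win_start + cand.start) - proj_start
            if abs(offset) > max_offset:
                continue
            if best is None or cand.score > best[0]:
                best = (cand.score, offset)
        out[species] = best
    return out


def conserve_hits(hits: Iterable[BindingSiteHit], pwms: Mapping[str, PWM],
                  blocks: Sequence[AlignmentBlock],
                  species_records: Mapping[str, Mapping[str, SequenceRecord]],
                  lam: float = DEFAULT_LAMBDA,
                  threshold_fraction: float = 0.75,
                  max_offset: int = MAX_OFFSET) -> list[ConservedHit]:
    """Score every reference hit with its cross-species support."""
    blocks = sort_and_check(blocks)
    out = []
    for hit in hits:
        species_hits = find_support(hit, pwms[hit.matrix_id], blocks,
                                    species_records,
                                    threshold_fraction=threshold_fraction,
                                    max_offset=max_offset)
        out.append(combine(hit, species_hits, lam=lam))
    return out


def read_conserved_bed(path: str | Path) -> list[ConservedHit]:
    """Read the extended BED written by :func:`write_conserved_bed`."""
    out: list[ConservedHit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            (seq_id, start, end, matrix_id, _, strand,
             combined, ref_score, sup_field) = line.rstrip("\n").split("\t")
            hit = BindingSiteHit(matrix_id, seq_id, int(start), int(end),
                                 strand, float(ref_score))
            support = []
            if sup_field != ".":
                for token in sup_field.split(";"):
                    species, _, rest = token.partition(":")
                    score, _, offset = rest.partition("@")
                    support.append(SpeciesSupport(species, float(score),
                                                  int(offset)))
            best = None
            best_score = 0.0
            for s in support:
                if s.score > best_score:
                    best_score, best = s.score, s.species
            out.append(ConservedHit(hit, tuple(support), float(combined), best))
    return out


def write_conserved_bed(chits: Sequence[ConservedHit], path: str | Path) -> None:
    """Extended BED: BED6 plus combined score and per-species support."""
    with open(path, "w") as fh:
        for ch in chits:
            sup = ";".join(f"{s.species}:{s.score:.3f}@{s.offset:+d}"
                           for s in ch.support) or "."
            fh.write(f"{ch.seq_id}\t{ch.start}\t{ch.end}\t{ch.matrix_id}\t"
                     f"{round(ch.combined_score * 100)}\t{ch.ref_hit.strand}\t"
                     f"{ch.combined_score:.4f}\t{ch.ref_hit.score:.4f}\t{sup}\n")
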