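"""Pan-vertebrate conservation filter and candidate ranking.

Each predicted CRM is anchored to the closest reference gene that has a
human ortholog H; the human search space is the interval spanned by H and
its two flanking genes (padded).  The CRM sequence is locally aligned to
that neighbourhood with the HOXD70 substitution matrix and affine gap
costs 400 (open) / 30 (extend) — the scoring scheme of BLASTZ, so the
published score scale applies.  A CRM passes when the alignment score
exceeds 2600 AND the percent identity exceeds 60 (both strict).

Passing CRMs are ranked by CRM score; the screen takes the top 10 plus 10
more spread through the top 200 at fixed rank positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .crm import CRM
from .genes import GeneModel
from .sequences import reverse_complement

ALIGN_SCORE_CUTOFF = 2600.0  # BLASTZ-scale units, strict
IDENTITY_CUTOFF = 60.0  # percent, strict
GAP_OPEN = 400
GAP_EXTEND = 30
NEIGHBORHOOD_PAD_BP = 10_000
#: Rank positions (1-based) of the spread candidate list within the top 200.
SPREAD_POSITIONS = (20, 40, 60, 81, 100, 120, 140, 159, 180, 200)


@dataclass(frozen=True)
class HumanAnchor:
    """The human neighbourhood a CRM is compared against."""

    crm_id: str
    ref_gene: str
    human_ortholog: str
    search_seq_id: str
    search_start: int
    search_end: int


@dataclass(frozen=True)
class ConservationCall:
    crm_id: str
    aln_score: float
    pct_identity: float

    @property
    def passes(self) -> bool:
        return passes_vertebrate_filter(self.aln_score, self.pct_identity)


def passes_vertebrate_filter(aln_score: float, pct_identity: float,
                             score_cutoff: float = ALIGN_SCORE_CUTOFF,
                             identity_cutoff: float = IDENTITY_CUTOFF) -> bool:
    """Strict inequalities: a score of exactly 2600 or 60% identity fails."""
    return aln_score > score_cutoff and pct_identity > identity_cutoff


def anchor(crm: CRM, ref_genes: Sequence[GeneModel],
           orthologs: Mapping[str, str],
           human_genes: Sequence[GeneModel],
           pad_bp: int = NEIGHBORHOOD_PAD_BP) -> HumanAnchor | None:
    """Anchor a CRM on the closest reference gene with a human ortholog.

    Returns ``None`` (with a warning) when no gene on the CRM's sequence
    has a human ortholog, or the ortholog is missing from the human gene
    table.
    """
    eligible = [g for g in ref_genes
                if g.seq_id == crm.seq_id and g.gene_id in orthologs]
    if not eligible:
        warnings.warn(f"{crm.crm_id}: no gene with a human ortholog on "
                      f"{crm.seq_id}; CRM unanchorable")
        return None
    nearest = min(eligible, key=lambda g: (abs(g.midpoint - crm.midpoint),
                                           g.start))
    human_id = orthologs[nearest.gene_id]
    by_id = {g.gene_id: g for g in human_genes}
    h = by_id.get(human_id)
    if h is None:
        warnings.warn(f"{crm.crm_id}: human ortholog {human_id} absent from "
                      "the human gene table; CRM unanchorable")
        return None
    neighbours = sorted((g for g in human_genes if g.seq_id == h.seq_id),
                        key=lambda g: (g.start, g.end))
    idx = neighbours.index(h)
    window = neighbours[max(0, idx - 1):idx + 2]
    start = max(0, min(g.start for g in window) - pad_bp)
    end = max(g.end for g in window) + pad_bp
    return HumanAnchor(crm.crm_id, nearest.gene_id, human_id,
                       h.seq_id, start, end)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("HOXD70")
    # affine gap of length k costs open + extend * k
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def align_to_human(crm_id: str, crm_seq: str, search_seq: str
                   ) -> ConservationCall:
    """Best local alignment of the CRM against the human neighbourhood.

    Both strands are tried; percent identity is matches over aligned
    columns (gap columns included) of the best-scoring alignment.
    """
    if not crm_seq or not search_seq:
        raise ValueError("alignment requires non-empty sequences")
    aligner = _aligner()
    best_score = float("-inf")
    best_identity = 0.0
    for query in (crm_seq.upper(), reverse_complement(crm_seq.upper())):
        alignments = aligner.align(search_seq.upper(), query)
        if alignments.score <= best_score:
            continue
        aln = alignments[0]
        counts = aln.counts()
        columns = aln.length  # aligned columns of the local alignment
        identity = 100.0 * counts.identities / columns if columns else 0.0
        best_score = float(alignments.score)
        best_identity = identity
    return ConservationCall(crm_id, best_score, best_identity)


def select_candidates(scored: Sequence[tuple[CRM, ConservationCall]],
                      spread_positions: Sequence[int] = SPREAD_POSITIONS,
                      passes_fn=None) -> dict[str, list[CRM]]:
    """Rank passing CRMs by score and pick the two candidate lists.

    ``top10`` is ranks 1-10; ``spread10`` the CRMs at the fixed rank
    positions within the top 200 (positions beyond the passing count are
    clipped with a warning).  Ties in score break towards the earlier
    genomic position.
    """
    passes_fn = passes_fn or (lambda call: call.passes)
    passing = [crm for crm, call in scored if passes_fn(call)]
    passing.sort(key=lambda c: (-c.score, c.seq_id, c.start))
    top10 = passing[:10]
    clipped = [p for p in spread_positions if p <= len(passing)]
    if len(clipped) < len(spread_positions):
        warnings.warn(f"only {len(passing)} passing CRMs; spread positions "
                      f"clipped to {clipped}")
    spread10 = [passing[p - 1] for p in clipped]
    return {"top10": top10, "spread10": spread10}
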