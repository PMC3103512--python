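"""Clustering conserved binding-site hits into cis-regulatory modules.

A CRM is a dense cluster of conserved homotypic (one matrix) or oligotypic
(a few matrices) binding sites.  Candidate windows of at most ``window_bp``
are scored and the best non-overlapping ones kept:

* oligotypic windows score the best hit of each of the top-K distinct
  matrices (default K = 5);
* homotypic windows (a single contributing matrix) score the top-K hits of
  that matrix, so single-factor clusters are not starved to one site.

The hits entering the score are the CRM's *contributing* hits; the CRM
score always re-derives as the sum of their combined scores.  Boundaries
are trimmed to the outermost contributing hits.  For experimental testing,
close-by CRMs are fused and extended by flanking sequence on each side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .conservation import ConservedHit

DEFAULT_WINDOW_BP = 1000
DEFAULT_K = 5
DEFAULT_MIN_HITS = 3
#: Default CRM score cutoff (bits).  Chosen so that a window must carry
#: conservation support: ``min_hits`` unconserved hits at the per-matrix
#: threshold cannot reach it (see docs/methods.md, threshold calibration).
DEFAULT_SCORE_THRESHOLD = 45.0
DEFAULT_FUSE_GAP_BP = 500
DEFAULT_FLANK_BP = 200


@dataclass
class CRM:
    """A predicted cis-regulatory module (pre-extension boundaries)."""

    crm_id: str
    seq_id: str
    start: int
    end: int
    score: float  # sum of contributing combined scores, bits
    tag_matrices: tuple[str, ...]
    hits: tuple[ConservedHit, ...]  # contributing hits only
    n_sites: int  # all conserved hits within the span

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class TestRegion:
    """A fused, flank-extended interval taken to the enhancer assay."""

    region_id: str
    seq_id: str
    start: int
    end: int
    source_crms: tuple[str, ...]
    flank: int


def score_window(hits: Sequence[ConservedHit], k: int = DEFAULT_K
                 ) -> tuple[float, list[ConservedHit]]:
    """Score one candidate window; returns (score, contributing hits).

    Oligotypic: best hit per matrix, top-k matrices.  Homotypic: top-k hits
    of the single matrix.  Ties break towards the leftmost hit.
    """
    if not hits:
        return 0.0, []
    by_matrix: dict[str, list[ConservedHit]] = {}
    for h in hits:
        by_matrix.setdefault(h.matrix_id, []).append(h)
    if len(by_matrix) == 1:
        pool = sorted(hits, key=lambda h: (-h.combined_score, h.start))
        contributing = sorted(pool[:k], key=lambda h: h.start)
    else:
        best_per = [min(group, key=lambda h: (-h.combined_score, h.start))
                    for group in by_matrix.values()]
        best_per.sort(key=lambda h: (-h.combined_score, h.start))
        contributing = sorted(best_per[:k], key=lambda h: h.start)
    return sum(h.combined_score for h in contributing), contributing


def call_crms(hits: Iterable[ConservedHit],
              window_bp: int = DEFAULT_WINDOW_BP,
              k: int = DEFAULT_K,
              min_hits: int = DEFAULT_MIN_HITS,
              score_threshold: float = DEFAULT_SCORE_THRESHOLD,
              id_prefix: str = "CRM") -> list[CRM]:
    """Sliding maximal-window clustering with greedy non-overlap selection.

    Every hit anchors a candidate window covering the hits that start
    within ``window_bp`` of it; candidates need at least ``min_hits`` hits
    and a score of at least ``score_threshold``.  Candidates are then taken
    greedily by descending score (leftmost wins ties), discarding any that
    overlap an already-accepted CRM.
    """
    per_seq: dict[str, list[ConservedHit]] = {}
    for h in hits:
        per_seq.setdefault(h.seq_id, []).append(h)
    candidates: list[tuple[float, str, int, int, list[ConservedHit], list[ConservedHit]]] = []
    for seq_id, seq_hits in per_seq.items():
        seq_hits.sort(key=lambda h: (h.start, h.end))
        starts = np.array([h.start for h in seq_hits])
        for i in range(len(seq_hits)):
            j = int(np.searchsorted(starts, starts[i] + window_bp, side="left"))
            window_hits = seq_hits[i:j]
            if len(window_hits) < min_hits:
                continue
            score, contributing = score_window(window_hits, k=k)
            if score < score_threshold or len(contributing) < 1:
                continue
            start = min(h.start for h in contributing)
            end = max(h.end for h in contributing)
            candidates.append((score, seq_id, start, end, contributing, window_hits))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    chosen: list[tuple[float, str, int, int, list[ConservedHit], list[ConservedHit]]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for cand in candidates:
        _, seq_id, start, end, _, _ = cand
        if any(start < e and s < end for s, e in occupied.get(seq_id, [])):
            continue
        chosen.append(cand)
        occupied.setdefault(seq_id, []).append((start, end))
    chosen.sort(key=lambda c: (c[1], c[2]))
    crms = []
    for idx, (score, seq_id, start, end, contributing, _) in enumerate(chosen, 1):
        in_span = [h for h in per_seq[seq_id] if h.start >= start and h.end <= end]
        tags = tuple(dict.fromkeys(h.matrix_id for h in contributing))
        crms.append(CRM(f"{id_prefix}{idx:05d}", seq_id, start, end,
                        float(score), tags, tuple(contributing), len(in_span)))
    return crms


def fuse_and_extend(crms: Sequence[CRM],
                    seq_lengths: Mapping[str, int],
                    fuse_gap_bp: int = DEFAULT_FUSE_GAP_BP,
                    flank_bp: int = DEFAULT_FLANK_BP,
                    id_prefix: str = "REG") -> list[TestRegion]:
    """Fuse CRMs separated by at most ``fuse_gap_bp`` and add flanks."""
    per_seq: dict[str, list[CRM]] = {}
    for c in crms:
        per_seq.setdefault(c.seq_id, []).append(c)
    regions = []
    counter = 0
    for seq_id in sorted(per_seq):
        group: list[CRM] = []
        for c in sorted(per_seq[seq_id], key=lambda c: c.start):
            if group and c.start - group[-1].end <= fuse_gap_bp:
                group.append(c)
                continue
            if group:
                counter += 1
                regions.append(_make_region(group, seq_lengths[seq_id],
                                            flank_bp, f"{id_prefix}{counter:04d}"))
            group = [c]
        if group:
            counter += 1
            regions.append(_make_region(group, seq_lengths[seq_id],
                                        flank_bp, f"{id_prefix}{counter:04d}"))
    return regions


def _make_region(group: list[CRM], seq_len: int, flank_bp: int,
                 region_id: str) -> TestRegion:
    start = max(0, min(c.start for c in group) - flank_bp)
    end = min(seq_len, max(c.end for c in group) + flank_bp)
    return TestRegion(region_id, group[0].seq_id, start, end,
                      tuple(c.crm_id for c in group), flank_bp)


def summarize(crms: Sequence[CRM]) -> dict:
    """Count, mean/median pre-extension length, mean sites per CRM."""
    if not crms:
        return {"count": 0, "mean_length": None, "median_length": None,
                "mean_sites": None}
    lengths = np.array([c.length for c in crms], dtype=float)
    sites = np.array([c.n_sites for c in crms], dtype=float)
    return {"count": len(crms),
            "mean_length": float(lengths.mean()),
            "median_length": float(np.median(lengths)),
            "mean_sites": float(sites.mean())}


def calibrate_score_threshold(hits: Sequence[ConservedHit],
                              seq_lengths: Mapping[str, int],
                              rng: np.random.Generator,
                              window_bp: int = DEFAULT_WINDOW_BP,
                              k: int = DEFAULT_K,
                              min_hits: int = DEFAULT_MIN_HITS,
                              n_shuffles: int = 20,
                              fpr: float = 0.01) -> float:
    """Score cutoff giving a window-level false-positive rate of ``fpr``.

    Hit positions are shuffled uniformly per sequence (scores kept),
    destroying clustering; the cutoff is the (1 - fpr) quantile of
    candidate-window scores under this null (0 when no null window ever
    reaches ``min_hits``).
    """
    from .scan import BindingSiteHit

    null_scores: list[float] = []
    hits = list(hits)
    for _ in range(n_shuffles):
        shuffled: list[ConservedHit] = []
        for h in hits:
            width = h.end - h.start
            pos = int(rng.integers(0, seq_lengths[h.seq_id] - width + 1))
            moved = BindingSiteHit(h.matrix_id, h.seq_id, pos, pos + width,
                                   h.ref_hit.strand, h.ref_hit.score)
            shuffled.append(ConservedHit(moved, h.support, h.combined_score,
                                         h.supporting_species))
        per_seq: dict[str, list[ConservedHit]] = {}
        for h in shuffled:
            per_seq.setdefault(h.seq_id, []).append(h)
        for seq_hits in per_seq.values():
            seq_hits.sort(key=lambda h: h.start)
            starts = np.array([h.start for h in seq_hits])
            for i in range(len(seq_hits)):
                j = int(np.searchsorted(starts, starts[i] + window_bp, "left"))
                if j - i >= min_hits:
                    null_scores.append(score_window(seq_hits[i:j], k=k)[0])
    if not null_scores:
        return 0.0
    return float(np.quantile(null_scores, 1.0 - fpr))


def write_crms_bed(crms: Sequence[CRM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in crms:
            fh.write(f"{c.seq_id}\t{c.start}\t{c.end}\t{c.crm_id}\t"
                     f"{round(c.score * 100)}\t+\n")


def write_crms_json(crms: Sequence[CRM], path: str | Path) -> None:
    """JSON sidecar with tag matrices and contributing hits."""
    payload = []
    for c in crms:
        payload.append({
            "crm_id": c.crm_id, "seq_id": c.seq_id, "start": c.start,
            "end": c.end, "score": c.score, "n_sites": c.n_sites,
            "tag_matrices": list(c.tag_matrices),
            "hits": [{"matrix_id": h.matrix_id, "start": h.start,
                      "end": h.end, "strand": h.ref_hit.strand,
                      "ref_score": h.ref_hit.score,
                      "combined_score": h.combined_score,
                      "supporting_species": h.supporting_species}
                     for h in c.hits]})
    Path(path).write_text(json.dumps(payload, indent=1))


def read_crms_json(path: str | Path) -> list[CRM]:
    """Rebuild CRMs from the JSON sidecar (per-species support not kept)."""
    from .scan import BindingSiteHit

    crms = []
    for entry in json.loads(Path(path).read_text()):
        hits = tuple(
            ConservedHit(BindingSiteHit(h["matrix_id"], entry["seq_id"],
                                        h["start"], h["end"], h["strand"],
                                        h["ref_score"]),
                         (), h["combined_score"], h.get("supporting_species"))
            for h in entry["hits"])
        crms.append(CRM(entry["crm_id"], entry["seq_id"], entry["start"],
                        entry["end"], entry["score"],
                        tuple(entry["tag_matrices"]), hits, entry["n_sites"]))
    return crms


def write_regions_bed(regions: Sequence[TestRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.region_id}\t0\t+\n")
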