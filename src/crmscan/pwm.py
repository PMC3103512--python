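"""Position-weight matrices: parsing, curation and log-odds scoring.

The matrix collection mirrors how genome-wide binding-site screens curate
public motif libraries: TRANSFAC flat files and JASPAR PFMs are pooled,
non-vertebrate TRANSFAC entries are dropped (a configurable allow-list keeps
selected invertebrate matrices for factors with vertebrate roles), matrices
promiscuously linked to more than two factors of one species are discarded,
and redundant matrices for a single factor are collapsed to the
highest-quality one.  Scoring uses a uniform background model, so the
log-odds of base b at position i is log2(p(i,b) / 0.25) bits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as bio_motifs

BASES = "ACGT"
UNIFORM_BG = 0.25
DEFAULT_PSEUDOCOUNT = 0.01

#: Scientific-name fragments treated as vertebrate when classifying the
#: factor species recorded on TRANSFAC BF lines.
VERTEBRATE_SPECIES_KEYWORDS = frozenset({
    "homo sapiens", "human",
    "mus musculus", "mouse",
    "rattus", "rat",
    "gallus", "chick",
    "xenopus", "clawed frog",
    "danio", "zebrafish",
    "oryzias", "medaka",
    "takifugu", "fugu",
    "tetraodon",
    "gasterosteus", "stickleback",
    "bos taurus", "cattle", "bovine",
    "sus scrofa", "pig",
    "oryctolagus", "rabbit",
    "cricetulus", "hamster",
    "canis", "dog",
    "ovis", "sheep",
    "monodelphis", "opossum",
    "vertebrata", "vertebrate",
})


class MatrixParseError(ValueError):
    """A matrix block that cannot be interpreted, with file/record context."""


@dataclass
class PWM:
    """A base-probability matrix for one transcription factor.

    ``probs`` is width x 4 (columns A, C, G, T), normalized with
    pseudocounts so every cell is strictly positive and each row sums to 1.
    """

    matrix_id: str
    tf_name: str
    probs: np.ndarray
    source: str  # transfac | jaspar | chip_derived
    quality: str | None = None
    species: tuple[str, ...] = ()
    tf_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"{self.matrix_id}: probs must be width x 4, width >= 1")
        if (self.probs <= 0).any():
            raise ValueError(f"{self.matrix_id}: probabilities must be > 0 "
                             "(apply pseudocounts)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.matrix_id}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, matrix_id: str, tf_name: str, counts: np.ndarray,
                    source: str, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                    **kw) -> "PWM":
        """Normalize a width x 4 count (or frequency) matrix.

        Each row is scaled to frequencies, then ``pseudocount`` is added per
        cell and the row renormalized, guaranteeing finite log-odds.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise MatrixParseError(f"{matrix_id}: expected width x 4 counts")
        totals = counts.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            raise MatrixParseError(f"{matrix_id}: zero-count column")
        freqs = counts / totals
        probs = (freqs + pseudocount) / (1.0 + 4 * pseudocount)
        return cls(matrix_id, tf_name, probs, source, **kw)

    def log_odds(self) -> np.ndarray:
        """Width x 4 bit scores against the uniform background."""
        return np.log2(self.probs / UNIFORM_BG)

    def max_score(self) -> float:
        """Best achievable bit score (sum of per-position row maxima)."""
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix_id, self.tf_name, self.probs[::-1, ::-1].copy(),
                   self.source, quality=self.quality, species=self.species,
                   tf_ids=self.tf_ids)


@dataclass
class MatrixCollection:
    """Curated matrices plus a report of everything that was rejected."""

    pwms: list[PWM]
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.pwms)

    def __len__(self) -> int:
        return len(self.pwms)

    def by_id(self) -> dict[str, PWM]:
        return {p.matrix_id: p for p in self.pwms}


_QUALITY_RANK = {c: i for i, c in enumerate("ABCDEF")}


def _quality_rank(quality: str | None) -> int:
    """Lower is better; unknown quality sorts last."""
    if quality is None:
        return len(_QUALITY_RANK) + 1
    q = quality.strip().upper()
    if q in _QUALITY_RANK:
        return _QUALITY_RANK[q]
    m = re.fullmatch(r"Q?(\d+)", q)
    if m:
        return int(m.group(1))
    return len(_QUALITY_RANK)


_BF_RE = re.compile(r"Species:\s*([^,.;]+)(?:,\s*([^.;]+))?")


def _parse_bf_line(line: str) -> tuple[str | None, str | None]:
    """Extract (tf_id_and_name, species) from a TRANSFAC BF line."""
    head = line.split(";", 1)[0].strip()
    m = _BF_RE.search(line)
    species = None
    if m:
        species = (m.group(2) or m.group(1)).strip().lower()
    return head or None, species


def _is_vertebrate(species: Sequence[str]) -> bool:
    named = [sp.lower() for sp in species if sp]
    if not named:
        return True  # no species metadata: keep (JASPAR core vertebrate etc.)
    for sp in named:
        if any(key in sp for key in VERTEBRATE_SPECIES_KEYWORDS):
            return True
    return False


def _parse_transfac(text: str, path: str,
                    pseudocount: float) -> tuple[list[PWM], list[tuple[str, str]]]:
    try:
        records = bio_motifs.parse(StringIO(text), "transfac", strict=False)
    except Exception as exc:  # malformed flat file
        raise MatrixParseError(f"{path}: cannot parse TRANSFAC file: {exc}") from exc
    pwms: list[PWM] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        matrix_id = rec.get("AC") or rec.get("ID") or "?"
        name = rec.get("ID") or matrix_id
        tf_name = rec.get("NA") or name
        # tf_ids and species are kept parallel, one entry per BF line
        species: list[str] = []
        tf_ids: list[str] = []
        for bf in rec.get("BF") or []:
            tf, sp = _parse_bf_line(bf)
            tf_ids.append(tf or "?")
            species.append(sp or "")
        quality = None
        m = re.search(r"_(Q\d|[A-F])$", str(name))
        if m:
            quality = m.group(1)
        counts = np.array([[rec.counts[b][i] for b in BASES]
                           for i in range(rec.counts.length)], dtype=float)
        try:
            pwms.append(PWM.from_counts(
                str(matrix_id), str(tf_name), counts, "transfac",
                pseudocount=pseudocount, quality=quality,
                species=tuple(species), tf_ids=tuple(tf_ids)))
        except MatrixParseError as exc:
            rejected.append((str(matrix_id), str(exc)))
    return pwms, rejected


def _parse_jaspar(text: str, path: str,
                  pseudocount: float) -> tuple[list[PWM], list[tuple[str, str]]]:
    try:
        records = bio_motifs.parse(StringIO(text), "jaspar")
    except Exception as exc:
        raise MatrixParseError(f"{path}: cannot parse JASPAR file: {exc}") from exc
    pwms: list[PWM] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        matrix_id = rec.matrix_id or rec.name
        counts = np.array([[rec.counts[b][i] for b in BASES]
                           for i in range(rec.counts.length)], dtype=float)
        try:
            pwms.append(PWM.from_counts(str(matrix_id), str(rec.name), counts,
                                        "jaspar", pseudocount=pseudocount))
        except MatrixParseError as exc:
            rejected.append((str(matrix_id), str(exc)))
    return pwms, rejected


def parse_matrices(paths: Iterable[str | Path], dialect: str,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   curate: bool = True,
                   allow_list: Iterable[str] = ()) -> MatrixCollection:
    """Parse matrix files and (optionally) apply the curation rules.

    Parameters
    ----------
    dialect:
        ``"transfac"`` for the flat-file format, ``"jaspar"`` for PFMs.
    allow_list:
        Matrix ids exempt from the non-vertebrate drop rule.
    """
    if dialect not in ("transfac", "jaspar"):
        raise ValueError(f"unknown matrix dialect {dialect!r}")
    pwms: list[PWM] = []
    rejected: list[tuple[str, str]] = []
    for path in paths:
        text = Path(path).read_text()
        parser = _parse_transfac if dialect == "transfac" else _parse_jaspar
        got, bad = parser(text, str(path), pseudocount)
        if not got and not bad and text.strip():
            raise MatrixParseError(
                f"{path}: no parseable {dialect} matrix records")
        pwms.extend(got)
        rejected.extend(bad)
    collection = MatrixCollection(pwms, rejected)
    if curate:
        collection = curate_matrices(collection, allow_list=allow_list)
    return collection


def curate_matrices(collection: MatrixCollection,
                    allow_list: Iterable[str] = ()) -> MatrixCollection:
    """Apply the curation rules to an already-parsed collection.

    1. Non-vertebrate matrices are removed unless allow-listed.
    2. Matrices linked to more than two distinct factors of one species are
       discarded as promiscuous.
    3. Among matrices sharing one factor name, only the highest-quality one
       is kept (ties keep the first seen).
    """
    allow = set(allow_list)
    rejected = list(collection.rejected)
    kept: list[PWM] = []
    for pwm in collection.pwms:
        if pwm.matrix_id not in allow and not _is_vertebrate(pwm.species):
            rejected.append((pwm.matrix_id, "non-vertebrate"))
            continue
        per_species: dict[str, set[str]] = {}
        for tf, sp in zip(pwm.tf_ids, pwm.species):
            per_species.setdefault(sp or "?", set()).add(tf)
        if any(len(tfs) > 2 for tfs in per_species.values()):
            rejected.append((pwm.matrix_id, "linked to >2 factors of one species"))
            continue
        kept.append(pwm)
    best: dict[str, PWM] = {}
    for pwm in kept:
        key = pwm.tf_name.upper()
        cur = best.get(key)
        if cur is None or _quality_rank(pwm.quality) < _quality_rank(cur.quality):
            if cur is not None:
                rejected.append((cur.matrix_id,
                                 f"superseded by higher quality {pwm.matrix_id}"))
            best[key] = pwm
        elif cur is not None and pwm is not cur:
            rejected.append((pwm.matrix_id,
                             f"lower quality than {cur.matrix_id}"))
    order = {id(p): i for i, p in enumerate(kept)}
    curated = sorted(best.values(), key=lambda p: order[id(p)])
    return MatrixCollection(curated, rejected)


def _export_counts(pwm: PWM, scale: int,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Integer counts that re-normalize to ``pwm.probs`` after pseudocounts."""
    freqs = np.clip(pwm.probs * (1.0 + 4 * pseudocount) - pseudocount, 0, None)
    return np.rint(freqs * scale).astype(int)


def write_jaspar_pfm(pwms: Iterable[PWM], path: str | Path,
                     scale: int = 100) -> None:
    """Write matrices in JASPAR multi-PFM format (integer pseudo-counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.matrix_id} {pwm.tf_name}\n")
            counts = _export_counts(pwm, scale)
            for j, base in enumerate(BASES):
                row = " ".join(str(v) for v in counts[:, j])
                fh.write(f"{base} [ {row} ]\n")


def write_transfac(pwms: Iterable[PWM], path: str | Path,
                   scale: int = 100) -> None:
    """Write matrices as a TRANSFAC flat file (counts scaled to integers)."""
    with open(path, "w") as fh:
        fh.write("VV  crmscan matrix export\nXX\n//\n")
        for pwm in pwms:
            fh.write(f"AC  {pwm.matrix_id}\nXX\nID  {pwm.matrix_id}\nXX\n")
            fh.write(f"NA  {pwm.tf_name}\nXX\n")
            for i, sp in enumerate(pwm.species):
                tf = pwm.tf_ids[i] if i < len(pwm.tf_ids) else pwm.tf_name
                fh.write(f"BF  {tf}; Species: {sp}.\n")
            if pwm.species:
                fh.write("XX\n")
            fh.write("P0      A      C      G      T\n")
            counts = _export_counts(pwm, scale)
            for i in range(pwm.width):
                a, c, g, t = counts[i]
                cons = BASES[int(pwm.probs[i].argmax())]
                fh.write(f"{i + 1:02d} {a:6d} {c:6d} {g:6d} {t:6d}      {cons}\n")
            fh.write("XX\n//\n")
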