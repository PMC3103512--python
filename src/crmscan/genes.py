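"""Gene models with transcription start sites, plus GFF3/BED12 readers.

Internally everything is 0-based half-open; GFF3 coordinates are converted
at the boundary.  The TSS is the strand-aware 5' end of the gene span.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import unquote


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    seq_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must precede end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            key, _, val = part.partition("=")
            out[key.strip()] = unquote(val.strip())
    return out


def read_gff3(path: str | Path, feature_types: Sequence[str] = ("gene",)
              ) -> list[GeneModel]:
    """Read gene features from GFF3 (1-based closed -> 0-based half-open)."""
    genes: list[GeneModel] = []
    wanted = set(feature_types)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seq_id, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in wanted:
                continue
            attributes = _gff3_attributes(attrs)
            gene_id = attributes.get("ID") or attributes.get("gene_id") \
                or f"{ftype}:{seq_id}:{start}"
            genes.append(GeneModel(gene_id, seq_id, int(start) - 1, int(end),
                                   strand if strand in "+-" else "+"))
    return genes


def read_cds_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """CDS intervals per sequence from GFF3, for coding-region masking."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != "CDS":
                continue
            out.setdefault(fields[0], []).append((int(fields[3]) - 1, int(fields[4])))
    return out


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Gene spans from BED12 (or BED6): chrom, start, end, name, score, strand."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{seq_id}:{start}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            genes.append(GeneModel(name, seq_id, start, end, strand))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path,
               source: str = "crmscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.seq_id}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """TSV with header gene_id, seq_id, start, end, strand (0-based)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "gene_id":
                continue
            gene_id, seq_id, start, end, strand = fields[:5]
            genes.append(GeneModel(gene_id, seq_id, int(start), int(end), strand))
    return genes


def genes_by_seq(genes: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.seq_id, []).append(g)
    for seq_genes in out.values():
        seq_genes.sort(key=lambda g: (g.start, g.end))
    return out
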