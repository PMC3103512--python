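"""Deterministic synthetic multi-species datasets for the whole pipeline.

The generator emulates the statistical structure every pipeline stage
assumes, at desk scale: a soft-masked reference genome with gene models,
planted clusters of binding sites for known matrices (the ground-truth
CRMs), three diverged comparison genomes carrying the planted sites at
controlled misalignment offsets, pairwise alignment blocks in both the
MAF and TSV dialects, human neighbourhood sequences in which a subset of
planted CRMs is embedded at high identity, ortholog tables, zebrafish
tissue annotations with controlled enrichment, and an injection-assay
table.  Everything derives from one seed; the same spec generates a
byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .conservation import AlignmentBlock, write_block_table
from .genes import GeneModel, write_gff3
from .pwm import PWM, write_jaspar_pfm, write_transfac
from .sequences import SequenceRecord, write_fasta

BASES = "ACGT"
COMPARISON_SPECIES = ("tetraodon", "stickleback", "fugu")

#: Consensus sequences of the built-in synthetic matrix set (width 10,
#: sharp consensus: one-mismatch sites still clear the default threshold).
_MATRIX_CONSENSUS = {
    "SYN01": ("tfa", "TGACGTCTAC"),
    "SYN02": ("tfb", "CCATGGTTGA"),
    "SYN03": ("tfc", "GATAAGGCAT"),
    "SYN04": ("tfd", "TTCGCACGAA"),
    "SYN05": ("tfe", "AGGTCACAGT"),
    "SYN06": ("tff", "CACCTGTTCG"),
}


def default_matrix_set(consensus_weight: int = 85) -> list[PWM]:
    """The built-in synthetic PWMs (counts: consensus 85, others 5 each)."""
    pwms = []
    for matrix_id, (tf, consensus) in _MATRIX_CONSENSUS.items():
        counts = np.full((len(consensus), 4), (100 - consensus_weight) / 3)
        for i, base in enumerate(consensus):
            counts[i, BASES.index(base)] = consensus_weight
        pwms.append(PWM.from_counts(matrix_id, tf, counts, "jaspar"))
    return pwms


@dataclass
class PlantedCRM:
    """Ground truth for one planted binding-site cluster."""

    crm_index: int
    seq_id: str
    start: int
    end: int
    matrix_ids: tuple[str, ...]
    site_starts: tuple[int, ...]
    site_matrices: tuple[str, ...]
    site_strands: tuple[str, ...]
    conserved_in: tuple[str, ...]
    offsets: dict[str, int]
    high_identity: bool
    nearest_gene: str | None = None


@dataclass
class FixtureSpec:
    """Generation parameters; the defaults are the standard study conditions."""

    seed: int = 0
    n_sequences: int = 2
    sequence_length: int = 50_000
    gc_content: float = 0.40
    genes_per_sequence: int = 8
    gene_length_range: tuple[int, int] = (800, 2500)
    gene_gap_range: tuple[int, int] = (1200, 4500)
    n_planted: int = 10
    sites_per_crm: int = 8
    site_gap_range: tuple[int, int] = (15, 40)
    n_oligotypic: int = 3  # planted CRMs mixing two matrices
    epsilon: float = 0.05  # per-base mutation of planted consensus sites
    species_extra_divergence: float = 0.05  # further divergence of site copies
    background_divergence: float = 0.30  # neutral divergence of comparison genomes
    max_planted_offset: int = 12
    n_high_identity: int = 6  # planted CRMs conserved to human
    human_identity: float = 0.85
    human_seq_length: int = 8000
    masked_fraction: float = 0.08
    repeat_length_range: tuple[int, int] = (200, 600)
    p_neuronal_conserved: float = 0.6
    p_neuronal_background: float = 0.3
    p_nonneuronal: float = 0.3
    n_injection_regions: int = 20
    n_injection_positive: int = 19
    vocabulary_size: int = 32
    vocabulary_labeled: int = 20

    def validate(self) -> None:
        if self.max_planted_offset > 20:
            raise ValueError("planted misalignment offsets must be <= 20 bp")
        if self.n_high_identity > self.n_planted:
            raise ValueError("n_high_identity cannot exceed n_planted")
        if self.n_planted % self.n_sequences:
            raise ValueError("n_planted must divide evenly over sequences")


NEURONAL_TERMS = ("brain", "spinal_cord")
NONNEURONAL_TERMS = ("pronephros", "somite")
TERM_PARENTS = {"brain": {"nervous_system"},
                "spinal_cord": {"nervous_system"}}
STAGE = "st20"


@dataclass
class FixtureBundle:
    """Everything `generate` produces, in memory."""

    spec: FixtureSpec
    pwms: list[PWM]
    ref_records: dict[str, SequenceRecord]
    species_records: dict[str, dict[str, SequenceRecord]]
    blocks: list[AlignmentBlock]
    genes: list[GeneModel]
    planted: list[PlantedCRM]
    human_records: dict[str, SequenceRecord]
    human_genes: list[GeneModel]
    human_orthologs: dict[str, str]  # reference gene -> human gene
    zf_orthologs: list[tuple[str, str, float]]  # zebrafish, reference, pct id
    annotations: list[tuple[str, str, str]]  # zebrafish gene, term, stage
    term_parents: dict[str, set[str]]
    injections: list[tuple[str, int, int, int]]
    line_annotations: dict[str, list[str]]
    vocabulary: list[str]

    @property
    def seq_lengths(self) -> dict[str, int]:
        return {s: len(r) for s, r in self.ref_records.items()}

    @property
    def masks(self) -> dict[str, np.ndarray]:
        return {s: r.mask for s, r in self.ref_records.items()}

    def truth(self) -> dict:
        return {
            "planted": [asdict(p) for p in self.planted],
            "n_planted": len(self.planted),
            "high_identity": [p.crm_index for p in self.planted
                              if p.high_identity],
            "vocabulary": self.vocabulary,
            "n_vocabulary_labeled": self.spec.vocabulary_labeled,
            "n_injection_positive": self.spec.n_injection_positive,
        }


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=n, p=probs)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float
            ) -> np.ndarray:
    out = codes.copy()
    flip = rng.random(out.size) < rate
    # shift by 1..3 guarantees a different base
    out[flip] = (out[flip] + rng.integers(1, 4, flip.sum())) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def generate(spec: FixtureSpec | None = None) -> FixtureBundle:
    """Generate the full bundle deterministically from ``spec.seed``."""
    spec = spec or FixtureSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pwms = default_matrix_set()
    consensus_codes = {p.matrix_id: np.array([BASES.index(b)
                                              for b in p.consensus()])
                       for p in pwms}

    ref_codes: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    planted: list[PlantedCRM] = []
    per_seq_planted = spec.n_planted // spec.n_sequences
    crm_index = 0
    for s in range(spec.n_sequences):
        seq_id = f"chr{s + 1}"
        codes = _random_dna(rng, spec.sequence_length, spec.gc_content)

        # genes laid left to right with random gaps; gaps host planted CRMs
        cursor = 1000
        seq_genes: list[GeneModel] = []
        gaps: list[tuple[int, int]] = []  # intergenic intervals
        for g in range(spec.genes_per_sequence):
            length = int(rng.integers(*spec.gene_length_range))
            gap = int(rng.integers(*spec.gene_gap_range))
            if cursor + length > spec.sequence_length - 1000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneModel(f"g{s + 1}_{g + 1}", seq_id, cursor,
                             cursor + length, strand)
            seq_genes.append(gene)
            gaps.append((cursor + length, min(cursor + length + gap,
                                              spec.sequence_length)))
            cursor += length + gap
        genes.extend(seq_genes)

        # plant CRMs centred in the widest intergenic gaps
        order = np.argsort([-(e - b) for b, e in gaps], kind="stable")
        chosen = sorted(int(order[i]) for i in range(per_seq_planted))
        for gi in chosen:
            gap_start, gap_end = gaps[gi]
            n_matrices = 2 if crm_index < spec.n_oligotypic else 1
            matrix_ids = tuple(
                pwms[int(i)].matrix_id
                for i in rng.choice(len(pwms), size=n_matrices, replace=False))
            site_gaps = rng.integers(*spec.site_gap_range,
                                     size=spec.sites_per_crm)
            widths = [consensus_codes[m].size for m in matrix_ids]
            span = int(sum(max(widths) + g for g in site_gaps))
            centre = (gap_start + gap_end) // 2
            start = max(gap_start + 100, centre - span // 2)
            site_starts: list[int] = []
            site_matrices: list[str] = []
            site_strands: list[str] = []
            pos = start
            for j in range(spec.sites_per_crm):
                m = matrix_ids[j % len(matrix_ids)]
                cons = consensus_codes[m]
                site = _mutate(rng, cons, spec.epsilon)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    site = _revcomp_codes(site)
                codes[pos:pos + site.size] = site
                site_starts.append(pos)
                site_matrices.append(m)
                site_strands.append(strand)
                pos += site.size + int(site_gaps[j])
            end = site_starts[-1] + consensus_codes[site_matrices[-1]].size
            n_conserved = int(rng.integers(2, 4))  # 2 or 3 species
            conserved_in = tuple(
                COMPARISON_SPECIES[int(i)]
                for i in sorted(rng.choice(3, size=n_conserved, replace=False)))
            offsets = {sp: int(rng.integers(-spec.max_planted_offset,
                                            spec.max_planted_offset + 1))
                       for sp in conserved_in}
            planted.append(PlantedCRM(crm_index, seq_id, start, end,
                                      matrix_ids, tuple(site_starts),
                                      tuple(site_matrices), tuple(site_strands),
                                      conserved_in, offsets,
                                      high_identity=False))
            crm_index += 1
        ref_codes[seq_id] = codes

    # the high-identity (human-conserved) subset is fixed up front
    high = rng.choice(len(planted), size=spec.n_high_identity, replace=False)
    for i in sorted(int(i) for i in high):
        planted[i].high_identity = True

    # masks: gene spans (coding proxy) plus random repeats avoiding plants
    ref_records: dict[str, SequenceRecord] = {}
    for seq_id, codes in ref_codes.items():
        record = SequenceRecord(seq_id, _to_str(codes))
        for gene in genes:
            if gene.seq_id == seq_id:
                record.add_masked_interval(gene.start, gene.end)
        target = int(spec.masked_fraction * spec.sequence_length)
        guard = [(p.start - 200, p.end + 200) for p in planted
                 if p.seq_id == seq_id]
        masked_bp = 0
        tries = 0
        while masked_bp < target and tries < 1000:
            tries += 1
            length = int(rng.integers(*spec.repeat_length_range))
            pos = int(rng.integers(0, spec.sequence_length - length))
            if any(pos < e and b < pos + length for b, e in guard):
                continue
            record.add_masked_interval(pos, pos + length)
            masked_bp += length
        ref_records[seq_id] = record

    # comparison genomes: neutral divergence plus planted-site copies at
    # the per-CRM offsets; alignment is the identity map (full-length block)
    species_records: dict[str, dict[str, SequenceRecord]] = {}
    blocks: list[AlignmentBlock] = []
    for species in COMPARISON_SPECIES:
        per_seq: dict[str, SequenceRecord] = {}
        for seq_id, codes in ref_codes.items():
            sp_codes = _mutate(rng, codes, spec.background_divergence)
            for p in planted:
                if p.seq_id != seq_id or species not in p.conserved_in:
                    continue
                offset = p.offsets[species]
                for site_start, m, strand in zip(p.site_starts,
                                                 p.site_matrices,
                                                 p.site_strands):
                    site = _mutate(rng, consensus_codes[m],
                                   spec.epsilon + spec.species_extra_divergence)
                    if strand == "-":
                        site = _revcomp_codes(site)
                    pos = site_start + offset
                    if 0 <= pos and pos + site.size <= sp_codes.size:
                        sp_codes[pos:pos + site.size] = site
            other_id = f"{species}_{seq_id}"
            per_seq[other_id] = SequenceRecord(other_id, _to_str(sp_codes))
            blocks.append(AlignmentBlock(
                seq_id, 0, codes.size, species, other_id, 0, codes.size,
                np.arange(codes.size, dtype=np.int64)))
        species_records[species] = per_seq

    # human neighbourhoods: one per reference gene; the nearest gene of
    # each high-identity planted CRM carries an embedded diverged copy
    near_two: dict[int, list[str]] = {}
    for p in planted:
        candidates = sorted(
            (g for g in genes if g.seq_id == p.seq_id),
            key=lambda g: (abs(g.midpoint - (p.start + p.end) / 2), g.start))
        p.nearest_gene = candidates[0].gene_id
        near_two[p.crm_index] = [g.gene_id for g in candidates[:2]]
    # In a real genome the neighbourhoods of adjacent genes overlap, so a
    # conserved element sits in the search space of both flanking genes;
    # per-gene neighbourhood sequences emulate that by each carrying a copy.
    embed_for: dict[str, list[PlantedCRM]] = {}
    for p in planted:
        if p.high_identity:
            for gene_id in near_two[p.crm_index]:
                embed_for.setdefault(gene_id, []).append(p)
    human_records: dict[str, SequenceRecord] = {}
    human_genes: list[GeneModel] = []
    human_orthologs: dict[str, str] = {}
    for gene in genes:
        hseq_id = f"hchr_{gene.gene_id}"
        hcodes = _random_dna(rng, spec.human_seq_length, spec.gc_content)
        copies = embed_for.get(gene.gene_id, [])
        for idx, p in enumerate(copies):
            fragment = ref_codes[p.seq_id][p.start - 50:p.end + 50]
            copy = _mutate(rng, fragment, 1.0 - spec.human_identity)
            slot = spec.human_seq_length // (len(copies) + 1)
            insert_at = min((idx + 1) * slot,
                            spec.human_seq_length - copy.size - 100)
            hcodes[insert_at:insert_at + copy.size] = copy
        human_records[hseq_id] = SequenceRecord(hseq_id, _to_str(hcodes))
        hgene = f"HS_{gene.gene_id.upper()}"
        human_genes.extend([
            GeneModel(f"{hgene}_L", hseq_id, 200, 900, "+"),
            GeneModel(hgene, hseq_id, 1200, 2200, "+"),
            GeneModel(f"{hgene}_R", hseq_id, spec.human_seq_length - 1200,
                      spec.human_seq_length - 400, "-")])
        human_orthologs[gene.gene_id] = hgene

    # zebrafish orthologs and tissue annotations with controlled enrichment
    conserved_linked = {p.nearest_gene for p in planted if p.high_identity}
    zf_orthologs: list[tuple[str, str, float]] = []
    annotations: list[tuple[str, str, str]] = []
    for i, gene in enumerate(genes):
        zf = f"zf_{gene.gene_id}"
        zf_orthologs.append((zf, gene.gene_id,
                             float(np.round(rng.uniform(60, 95), 1))))
        if i % 5 == 0 and i + 1 < len(genes):
            # a second, lower-identity ortholog exercises the resolver
            zf_orthologs.append((zf, genes[i + 1].gene_id,
                                 float(np.round(rng.uniform(30, 55), 1))))
        p_neuronal = (spec.p_neuronal_conserved
                      if gene.gene_id in conserved_linked
                      else spec.p_neuronal_background)
        for term in NEURONAL_TERMS:
            if rng.random() < p_neuronal:
                annotations.append((zf, term, STAGE))
        for term in NONNEURONAL_TERMS:
            if rng.random() < spec.p_nonneuronal:
                annotations.append((zf, term, STAGE))

    injections = _injection_table(rng, spec)
    vocabulary = [f"neuro_{i + 1:02d}" for i in range(spec.vocabulary_size)]
    labeled = [vocabulary[int(i)]
               for i in sorted(rng.choice(spec.vocabulary_size,
                                          size=spec.vocabulary_labeled,
                                          replace=False))]
    line_annotations: dict[str, list[str]] = {}
    for i, term in enumerate(labeled):
        line = f"line{i % 8 + 1:02d}"
        line_annotations.setdefault(line, []).append(term)

    return FixtureBundle(spec, pwms, ref_records, species_records, blocks,
                         genes, planted, human_records, human_genes,
                         human_orthologs, zf_orthologs, annotations,
                         dict(TERM_PARENTS), injections, line_annotations,
                         vocabulary)


def _injection_table(rng: np.random.Generator, spec: FixtureSpec
                     ) -> list[tuple[str, int, int, int]]:
    """Embryo counts for the screen: exactly n_injection_positive positives."""
    rows = []
    for i in range(spec.n_injection_regions):
        n_alive = int(rng.integers(60, 101))
        n_lens = int(rng.integers(max(25, n_alive // 3), int(n_alive * 0.7)))
        if i < spec.n_injection_positive:
            rate = rng.uniform(0.55, 0.85)
            n_specific = max(MIN_POSITIVE_FISH,
                             min(n_lens, int(round(rate * n_lens))))
        else:
            n_specific = int(round(0.25 * n_lens))  # clear negative
        rows.append((f"region{i + 1:02d}", n_alive, n_lens, n_specific))
    return rows


MIN_POSITIVE_FISH = 10


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, str]:
    """Write every fixture file; returns the file manifest (name -> path)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def note(name: str, path: Path) -> Path:
        manifest[name] = str(path)
        return path

    write_fasta(bundle.ref_records.values(), note("reference_fasta",
                                                  out / "reference.fa"))
    for species, records in bundle.species_records.items():
        write_fasta(records.values(), note(f"{species}_fasta",
                                           out / f"{species}.fa"))
    write_gff3(bundle.genes, note("genes_gff3", out / "genes.gff3"))
    write_jaspar_pfm(bundle.pwms, note("matrices_jaspar", out / "matrices.pfm"))
    write_transfac(bundle.pwms, note("matrices_transfac", out / "matrices.dat"))
    write_block_table(bundle.blocks, note("blocks_tsv", out / "blocks.tsv"))
    _write_maf(bundle, note("blocks_maf", out / "blocks.maf"))
    write_fasta(bundle.human_records.values(), note("human_fasta",
                                                    out / "human.fa"))
    with open(note("human_genes", out / "human_genes.tsv"), "w") as fh:
        fh.write("gene_id\tseq_id\tstart\tend\tstrand\n")
        for g in bundle.human_genes:
            fh.write(f"{g.gene_id}\t{g.seq_id}\t{g.start}\t{g.end}\t{g.strand}\n")
    with open(note("human_orthologs", out / "orthologs_human.tsv"), "w") as fh:
        fh.write("#reference_gene\thuman_gene\tpct_identity\n")
        for ref_gene, human_gene in bundle.human_orthologs.items():
            fh.write(f"{ref_gene}\t{human_gene}\t85.0\n")
    with open(note("zf_orthologs", out / "orthologs_zebrafish.tsv"), "w") as fh:
        fh.write("#zebrafish_gene\treference_gene\tpct_identity\n")
        for zf, ref_gene, pct in bundle.zf_orthologs:
            fh.write(f"{zf}\t{ref_gene}\t{pct}\n")
    with open(note("annotations", out / "annotations.tsv"), "w") as fh:
        fh.write("#gene_id\tterm\tstage\n")
        for gene_id, term, stage in bundle.annotations:
            fh.write(f"{gene_id}\t{term}\t{stage}\n")
    with open(note("ontology", out / "ontology.tsv"), "w") as fh:
        fh.write("#child\tparent\n")
        for child, parents in sorted(bundle.term_parents.items()):
            for parent in sorted(parents):
                fh.write(f"{child}\t{parent}\n")
    with open(note("injections", out / "injections.tsv"), "w") as fh:
        fh.write("region_id\tn_alive\tn_lens\tn_specific\n")
        for row in bundle.injections:
            fh.write("\t".join(str(v) for v in row) + "\n")
    with open(note("line_annotations", out / "line_annotations.tsv"), "w") as fh:
        fh.write("#line_id\tterm\n")
        for line, terms in sorted(bundle.line_annotations.items()):
            for term in terms:
                fh.write(f"{line}\t{term}\n")
    with open(note("vocabulary", out / "vocabulary.txt"), "w") as fh:
        fh.write("\n".join(bundle.vocabulary) + "\n")
    Path(note("truth", out / "truth.json")).write_text(
        json.dumps(bundle.truth(), indent=1, sort_keys=True))
    return manifest


def _write_maf(bundle: FixtureBundle, path: Path) -> None:
    """Pairwise MAF: one block per (reference sequence, species)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for block in bundle.blocks:
            ref = bundle.ref_records[block.ref_seq_id]
            other = bundle.species_records[block.species][block.other_seq_id]
            ref_text = ref.sequence[block.ref_start:block.ref_end]
            other_text = other.sequence[block.other_start:block.other_end]
            fh.write("a score=0\n")
            fh.write(f"s ref.{block.ref_seq_id} {block.ref_start} "
                     f"{len(ref_text)} + {len(ref)} {ref_text}\n")
            fh.write(f"s {block.species}.{block.other_seq_id} "
                     f"{block.other_start} {len(other_text)} + "
                     f"{len(other)} {other_text}\n\n")
    # identity blocks only: gapped MAF round-tripping is covered by the
    # TSV dialect, whose cigar strings encode arbitrary gaps


def evaluate_recovery(predicted, planted: Sequence[PlantedCRM]
                      ) -> dict[str, float]:
    """Recall/precision of predicted CRMs against planted intervals."""
    def overlaps(c, p) -> bool:
        return c.seq_id == p.seq_id and c.start < p.end and p.start < c.end

    recovered = sum(1 for p in planted
                    if any(overlaps(c, p) for c in predicted))
    true_pred = sum(1 for c in predicted
                    if any(overlaps(c, p) for p in planted))
    recall = recovered / len(planted) if planted else 0.0
    precision = true_pred / len(predicted) if predicted else 0.0
    return {"recall": recall, "precision": precision,
            "n_predicted": len(predicted), "n_planted": len(planted)}


def simulate_enrichment_dataset(rng: np.random.Generator,
                                n_conserved: int = 60,
                                n_background: int = 240,
                                p_neuronal_conserved: float = 0.6,
                                p_neuronal_background: float = 0.3,
                                p_nonneuronal: float = 0.3
                                ) -> tuple[list[str], list[str],
                                           dict[str, set[tuple[str, str]]]]:
    """CRM-level term sets with planted neuronal enrichment.

    Neuronal terms appear at ``p_neuronal_conserved`` among conserved CRMs
    versus ``p_neuronal_background`` in the background (2x by default);
    non-neuronal terms at parity.  Ontology closure (nervous_system) is
    applied.  Returns (conserved ids, all ids, per-CRM term sets).
    """
    conserved = [f"VC{i:04d}" for i in range(n_conserved)]
    background = [f"BG{i:04d}" for i in range(n_background)]
    crm_terms: dict[str, set[tuple[str, str]]] = {}
    for cid in conserved + background:
        p_neuro = (p_neuronal_conserved if cid.startswith("VC")
                   else p_neuronal_background)
        terms: set[tuple[str, str]] = set()
        for term in NEURONAL_TERMS:
            if rng.random() < p_neuro:
                terms.add((term, STAGE))
                for parent in TERM_PARENTS.get(term, ()):
                    terms.add((parent, STAGE))
        for term in NONNEURONAL_TERMS:
            if rng.random() < p_nonneuronal:
                terms.add((term, STAGE))
        crm_terms[cid] = terms
    return conserved, conserved + background, crm_terms
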