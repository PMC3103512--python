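"""Stage orchestration: one config, fixed output names, a run manifest.

Stages (in pipeline order): scan -> conserve -> call -> filter / context /
enrich, plus the independent qc stage.  ``run("all", ...)`` chains them.
Each stage reads the upstream stage's files from the run directory, so
stages can also be re-run individually; a missing upstream file raises an
error naming the stage to run first.  All randomness flows from the single
config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import assay, context, crm, enrichment, vertebrate
from .conservation import (conserve_hits, read_block_table, read_maf,
                           read_conserved_bed, write_conserved_bed)
from .genes import read_cds_intervals, read_gene_table, read_gff3
from .pwm import parse_matrices
from .scan import read_hits_bed, scan_all, write_hits_bed
from .sequences import read_fasta

logger = logging.getLogger("crmscan")

STAGES = ("scan", "conserve", "call", "filter", "context", "enrich", "qc")

#: Input files a stage needs, by config key.
_INPUT_KEYS = {
    "scan": ("reference_fasta", "matrices"),
    "conserve": ("reference_fasta", "matrices", "blocks", "species_fastas"),
    "call": (),
    "filter": ("reference_fasta", "genes_gff3", "human_fasta",
               "human_genes", "human_orthologs"),
    "context": ("reference_fasta", "genes_gff3"),
    "enrich": ("genes_gff3", "zf_orthologs", "annotations"),
    "qc": ("injections",),
}

_UPSTREAM = {"conserve": ("scan", "hits.bed"),
             "call": ("conserve", "conserved.bed"),
             "filter": ("call", "crms.json"),
             "context": ("call", "crms.json"),
             "enrich": ("call", "crms.json")}


@dataclass
class PipelineConfig:
    """All inputs and stage parameters; unknown keys are rejected."""

    inputs: dict = field(default_factory=dict)
    threshold_fraction: float = 0.75
    lam: float = 0.1
    max_offset: int = 20
    window_bp: int = 1000
    k: int = 5
    min_hits: int = 3
    score_threshold: float = crm.DEFAULT_SCORE_THRESHOLD
    fuse_gap_bp: int = 500
    flank_bp: int = 200
    align_score_cutoff: float = 2600.0
    identity_cutoff: float = 60.0
    min_conserved: int = 20
    fdr: float = 0.05
    n_rand: int = 100
    seed: int = 0
    matrix_dialect: str = "jaspar"

    def __post_init__(self) -> None:
        checks = [
            (0 < self.threshold_fraction <= 1, "threshold_fraction in (0, 1]"),
            (self.lam >= 0, "lam must be >= 0"),
            (0 <= self.max_offset <= 20, "max_offset in [0, 20]"),
            (self.window_bp > 0, "window_bp must be positive"),
            (self.k >= 1, "k must be >= 1"),
            (self.min_hits >= 1, "min_hits must be >= 1"),
            (self.fuse_gap_bp >= 0, "fuse_gap_bp must be >= 0"),
            (self.flank_bp >= 0, "flank_bp must be >= 0"),
            (0 < self.fdr < 1, "fdr in (0, 1)"),
            (self.n_rand >= 1, "n_rand must be >= 1"),
            (self.matrix_dialect in ("jaspar", "transfac"),
             "matrix_dialect must be jaspar or transfac"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(f"invalid config: {message}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class MissingUpstreamError(RuntimeError):
    pass


def _require_inputs(config: PipelineConfig, stage: str) -> None:
    missing = [k for k in _INPUT_KEYS[stage] if k not in config.inputs]
    if missing:
        raise ValueError(f"stage {stage!r} needs input paths for: {missing}")


def _require_upstream(run_dir: Path, stage: str) -> Path:
    upstream, fname = _UPSTREAM[stage]
    path = run_dir / fname
    if not path.exists():
        raise MissingUpstreamError(
            f"stage {stage!r} needs {fname}; run stage {upstream!r} first")
    return path


def _load_reference(config: PipelineConfig):
    records = read_fasta(config.inputs["reference_fasta"])
    gff = config.inputs.get("genes_gff3")
    if gff:
        # mask annotated coding sequence on top of soft-masked repeats
        cds = read_cds_intervals(gff)
        spans = {g.seq_id: [] for g in read_gff3(gff)}
        for g in read_gff3(gff):
            spans[g.seq_id].append((g.start, g.end))
        for seq_id, record in records.items():
            for start, end in cds.get(seq_id, []) + spans.get(seq_id, []):
                record.add_masked_interval(start, min(end, len(record)))
    return records


def _load_matrices(config: PipelineConfig):
    paths = config.inputs["matrices"]
    if isinstance(paths, str):
        paths = [paths]
    return parse_matrices(paths, config.matrix_dialect)


def _load_blocks(config: PipelineConfig):
    path = str(config.inputs["blocks"])
    if path.endswith(".maf"):
        return read_maf(path)
    return read_block_table(path)


def run(stage: str, config: PipelineConfig, run_dir: str | Path
        ) -> dict[str, str]:
    """Run one stage (or ``"all"``); returns the output manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if stage == "all":
        outputs: dict[str, str] = {}
        for s in STAGES:
            outputs.update(run(s, config, run_dir))
        outputs.update(_write_manifest(config, run_dir, outputs))
        return outputs
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    _require_inputs(config, stage)
    logger.info("running stage %s", stage)
    return _STAGE_FUNCS[stage](config, run_dir)


def _stage_scan(config: PipelineConfig, run_dir: Path) -> dict[str, str]:
    records = _load_reference(config)
    pwms = _load_matrices(config)
    hits = scan_all(records.values(), pwms,
                    threshold_fraction=config.threshold_fraction)
    out = run_dir / "hits.bed"
    write_hits_bed(hits, out)
    logger.info("scan: %d hits from %d matrices", len(hits), len(pwms))
    return {"hits": str(out)}


def _stage_conserve(config: PipelineConfig, run_dir: Path) -> dict[str, str]:
    hits_path = _require_upstream(run_dir, "conserve")
    hits = read_hits_bed(hits_path)
    pwms = _load_matrices(config).by_id()
    blocks = _load_blocks(config)
    species_records = {species: read_fasta(path, mask_lowercase=False)
                       for species, path in config.inputs["species_fastas"].items()}
    chits = conserve_hits(hits, pwms, blocks, species_records,
                          lam=config.lam,
                          threshold_fraction=config.threshold_fraction,
                          max_offset=config.max_offset)
    out = run_dir / "conserved.bed"
    write_conserved_bed(chits, out)
    return {"conserved": str(out)}


def _stage_call(config: PipelineConfig, run_dir: Path) -> dict[str, str]:
    chits = read_conserved_bed(_require_upstream(run_dir, "call"))
    crms = crm.call_crms(chits, window_bp=config.window_bp, k=config.k,
                         min_hits=config.min_hits,
                         score_threshold=config.score_threshold)
    records = _load_reference(config)
    seq_lengths = {s: len(r) for s, r in records.items()}
    regions = crm.fuse_and_extend(crms, seq_lengths,
                                  fuse_gap_bp=config.fuse_gap_bp,
                                  flank_bp=config.flank_bp)
    crm.write_crms_bed(crms, run_dir / "crms.bed")
    crm.write_crms_json(crms, run_dir / "crms.json")
    crm.write_regions_bed(regions, run_dir / "regions.bed")
    (run_dir / "crm_summary.json").write_text(
        json.dumps(crm.summarize(crms), indent=1))
    logger.info("call: %d CRMs, %d test regions", len(crms), len(regions))
    return {"crms": str(run_dir / "crms.bed"),
            "crms_json": str(run_dir / "crms.json"),
            "regions": str(run_dir / "regions.bed"),
            "crm_summary": str(run_dir / "crm_summary.json")}


def _stage_filter(config: PipelineConfig, run_dir: Path) -> dict[str, str]:
    crms = crm.read_crms_json(_require_upstream(run_dir, "filter"))
    records = _load_reference(config)
    genes = read_gff3(config.inputs["genes_gff3"])
    human_genes = read_gene_table(config.inputs["human_genes"])
    human_records = read_fasta(config.inputs["human_fasta"],
                               mask_lowercase=False)
    orthologs: dict[str, str] = {}
    with open(config.inputs["human_orthologs"]) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            ref_gene, human_gene = line.split("\t")[:2]
            orthologs[ref_gene] = human_gene.strip()
    calls = []
    for c in crms:
        anchor = vertebrate.anchor(c, genes, orthologs, human_genes)
        if anchor is None:
            calls.append((c, None))
            continue
        crm_seq = records[c.seq_id].sequence[c.start:c.end]
        search_record = human_records[anchor.search_seq_id]
        search_seq = search_record.sequence[
            anchor.search_start:min(anchor.search_end, len(search_record))]
        calls.append((c, vertebrate.align_to_human(c.crm_id, crm_seq,
                                                   search_seq)))
    def passes(call) -> bool:
        return vertebrate.passes_vertebrate_filter(
            call.aln_score, call.pct_identity,
            score_cutoff=config.align_score_cutoff,
            identity_cutoff=config.identity_cutoff)

    with open(run_dir / "conservation_calls.tsv", "w") as fh:
        fh.write("crm_id\taln_score\tpct_identity\tpasses\n")
        for c, call in calls:
            if call is None:
                fh.write(f"{c.crm_id}\tNA\tNA\tunanchorable\n")
            else:
                fh.write(f"{call.crm_id}\t{call.aln_score:.1f}\t"
                         f"{call.pct_identity:.2f}\t{passes(call)}\n")
    scored = [(c, call) for c, call in calls if call is not None]
    selection = vertebrate.select_candidates(scored, passes_fn=passes)
    with open(run_dir / "candidates.tsv", "w") as fh:
        fh.write("list\trank\tcrm_id\tseq_id\tstart\tend\tscore\n")
        for name, members in selection.items():
            for rank, c in enumerate(members, 1):
                fh.write(f"{name}\t{rank}\t{c.crm_id}\t{c.seq_id}\t"
                         f"{c.start}\t{c.end}\t{c.score:.3f}\n")
    return {"conservation_calls": str(run_dir / "conservation_calls.tsv"),
            "candidates": str(run_dir / "candidates.tsv")}


def _stage_context(config: PipelineConfig, run_dir: Path) -> dict[str, str]:
    crms = crm.read_crms_json(_require_upstream(run_dir, "context"))
    genes = read_gff3(config.inputs["genes_gff3"])
    records = _load_reference(config)
    seq_lengths = {s: len(r) for s, r in records.items()}
    masks = {s: r.mask for s, r in records.items()}
    result = context.randomize_and_test(
        crms, genes, seq_lengths, masks=masks, n_rand=config.n_rand,
        seed=np.random.default_rng(config.seed))
    payload = {"observed": result.observed.as_dict(),
               "empirical_p": result.empirical_p,
               "p_greater": result.p_greater,
               "p_less": result.p_less,
               "direction": result.direction,
               "n_randomizations": config.n_rand}
    out = run_dir / "genomic_context.json"
    out.write_text(json.dumps(payload, indent=1))
    return {"genomic_context": str(out)}


def _stage_enrich(config: PipelineConfig, run_dir: Path) -> dict[str, str]:
    crms = crm.read_crms_json(_require_upstream(run_dir, "enrich"))
    calls_path = run_dir / "conservation_calls.tsv"
    if not calls_path.exists():
        raise MissingUpstreamError(
            "stage 'enrich' needs conservation_calls.tsv; run stage 'filter' first")
    genes = read_gff3(config.inputs["genes_gff3"])
    ortho = enrichment.resolve_orthologs(
        enrichment.read_ortholog_table(config.inputs["zf_orthologs"]))
    annotations = enrichment.read_annotations(config.inputs["annotations"])
    parents = {}
    if config.inputs.get("ontology"):
        parents = enrichment.read_term_parents(config.inputs["ontology"])
    gene_terms = enrichment.transfer_annotations(annotations, ortho)
    crm_terms = enrichment.annotate_crms(crms, genes, gene_terms, parents)
    conserved = []
    with open(calls_path) as fh:
        next(fh)
        for line in fh:
            crm_id, _, _, passes = line.rstrip("\n").split("\t")
            if passes == "True":
                conserved.append(crm_id)
    results = enrichment.test_enrichment(conserved, [c.crm_id for c in crms],
                                         crm_terms,
                                         min_conserved=config.min_conserved,
                                         fdr=config.fdr)
    out = run_dir / "enrichment.tsv"
    if results:
        enrichment.write_enrichment_tsv(results, out)
    else:
        out.write_text("term\tstage\ta\tb\tc\td\tp\tq\tsignificant\n")
    return {"enrichment": str(out)}


def _stage_qc(config: PipelineConfig, run_dir: Path) -> dict[str, str]:
    experiments = assay.read_injection_table(config.inputs["injections"])
    calls = [assay.call_activity(e) for e in experiments]
    assay.write_activity_table(calls, run_dir / "activity.tsv")
    summary = assay.summarize_screen(calls)
    lines_path = config.inputs.get("line_annotations")
    vocab_path = config.inputs.get("vocabulary")
    if lines_path and vocab_path:
        line_annotations: dict[str, list[str]] = {}
        with open(lines_path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                line_id, term = line.rstrip("\n").split("\t")[:2]
                line_annotations.setdefault(line_id, []).append(term)
        vocabulary = [l.strip() for l in open(vocab_path) if l.strip()]
        summary["ontology_coverage"] = assay.ontology_coverage(
            line_annotations, vocabulary)
    (run_dir / "screen_summary.json").write_text(json.dumps(summary, indent=1))
    return {"activity": str(run_dir / "activity.tsv"),
            "screen_summary": str(run_dir / "screen_summary.json")}


_STAGE_FUNCS = {"scan": _stage_scan, "conserve": _stage_conserve,
                "call": _stage_call, "filter": _stage_filter,
                "context": _stage_context, "enrich": _stage_enrich,
                "qc": _stage_qc}


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: PipelineConfig, run_dir: Path,
                    outputs: Mapping[str, str]) -> dict[str, str]:
    from . import __version__

    def hash_value(value):
        if isinstance(value, dict):
            return {k: hash_value(v) for k, v in value.items()}
        if isinstance(value, (list, tuple)):
            return [hash_value(v) for v in value]
        return _sha256(value) if Path(str(value)).exists() else None

    manifest = {
        "version": __version__,
        "parameters": {k: v for k, v in config.to_dict().items()
                       if k != "inputs"},
        "input_hashes": {k: hash_value(v) for k, v in config.inputs.items()},
        "output_hashes": {k: _sha256(v) for k, v in outputs.items()},
        "stages": list(STAGES),
    }
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"manifest": str(path)}
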