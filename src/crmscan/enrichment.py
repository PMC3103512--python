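"""Ortholog-transferred tissue annotation and CRM enrichment testing.

Zebrafish in-situ expression annotations are transferred to reference
genes through an ortholog table (one reference gene per zebrafish gene,
the highest-identity one).  Each CRM inherits the annotation of the
closest of its two flanking genes, regardless of distance, with ontology
closure applied so a term also counts for all its ancestors ("and its
subparts").  Vertebrate-conserved CRMs are then tested per (term, stage)
against the remaining predicted CRMs with a one-sided Fisher exact test,
and Benjamini-Hochberg control at a 5% false-discovery rate; only terms
carried by at least 20 conserved CRMs are tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genes import GeneModel

MIN_CONSERVED = 20
FDR = 0.05


@dataclass(frozen=True)
class TissueAnnotation:
    gene_id: str
    term: str
    stage: str


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    stage: str
    a: int  # conserved CRMs annotated
    b: int  # conserved CRMs not annotated
    c: int  # background CRMs annotated
    d: int  # background CRMs not annotated
    p: float
    q: float
    significant: bool


def resolve_orthologs(table: pd.DataFrame | Iterable[tuple[str, str, float]]
                      ) -> dict[str, str]:
    """One reference gene per zebrafish gene: the highest-identity ortholog.

    Accepts a DataFrame with columns (zebrafish_gene, reference_gene,
    pct_identity) or an iterable of such rows.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table, columns=["zebrafish_gene",
                                             "reference_gene", "pct_identity"])
    idx = table.groupby("zebrafish_gene")["pct_identity"].idxmax()
    best = table.loc[idx]
    return dict(zip(best["zebrafish_gene"], best["reference_gene"]))


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["zebrafish_gene", "reference_gene", "pct_identity"],
                     header=None)
    if df.iloc[0, 0] in ("zebrafish_gene", "zf_gene"):  # tolerated header row
        df = df.iloc[1:].reset_index(drop=True)
    df["pct_identity"] = df["pct_identity"].astype(float)
    return df


def read_annotations(path: str | Path) -> list[TissueAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["gene_id", "term", "stage"], header=None, dtype=str)
    if df.iloc[0, 0] == "gene_id":
        df = df.iloc[1:]
    return [TissueAnnotation(r.gene_id, r.term, r.stage)
            for r in df.itertuples()]


def read_term_parents(path: str | Path) -> dict[str, set[str]]:
    """Parent table (child TAB parent per line) for ontology closure."""
    parents: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            child, parent = line.rstrip("\n").split("\t")[:2]
            if child == "child":
                continue
            parents.setdefault(child, set()).add(parent)
    return parents


def read_obo_parents(path: str | Path) -> dict[str, set[str]]:
    """Optional OBO input: is_a and part_of edges as a parent table."""
    import re

    parents: dict[str, set[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                current = None
            elif line.startswith("id:"):
                current = line[3:].strip()
            elif current and line.startswith("is_a:"):
                parents.setdefault(current, set()).add(line[5:].split("!")[0].strip())
            elif current and line.startswith("relationship: part_of"):
                m = re.match(r"relationship:\s*part_of\s+(\S+)", line)
                if m:
                    parents.setdefault(current, set()).add(m.group(1))
    return parents


def term_closure(term: str, parents: Mapping[str, set[str]]) -> set[str]:
    """The term plus all its ancestors (a subpart counts for the whole)."""
    out = {term}
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for parent in parents.get(node, ()):
            if parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def transfer_annotations(annotations: Sequence[TissueAnnotation],
                         ortholog_map: Mapping[str, str]
                         ) -> dict[str, set[tuple[str, str]]]:
    """Zebrafish gene annotations -> reference gene (term, stage) sets."""
    out: dict[str, set[tuple[str, str]]] = {}
    for ann in annotations:
        ref_gene = ortholog_map.get(ann.gene_id)
        if ref_gene is not None:
            out.setdefault(ref_gene, set()).add((ann.term, ann.stage))
    return out


def closest_gene(crm, genes: Sequence[GeneModel]) -> GeneModel | None:
    """Closest of the two flanking genes by midpoint distance.

    Ties break towards the upstream (earlier-coordinate) gene; distance is
    irrelevant beyond choosing the closer flank.
    """
    on_seq = sorted((g for g in genes if g.seq_id == crm.seq_id),
                    key=lambda g: (g.midpoint, g.start))
    if not on_seq:
        return None
    upstream = None
    downstream = None
    for g in on_seq:
        if g.midpoint <= crm.midpoint:
            upstream = g
        elif downstream is None:
            downstream = g
    if upstream is None:
        return downstream
    if downstream is None:
        return upstream
    d_up = abs(crm.midpoint - upstream.midpoint)
    d_down = abs(downstream.midpoint - crm.midpoint)
    return upstream if d_up <= d_down else downstream


def annotate_crms(crms, genes: Sequence[GeneModel],
                  gene_terms: Mapping[str, set[tuple[str, str]]],
                  parents: Mapping[str, set[str]] | None = None
                  ) -> dict[str, set[tuple[str, str]]]:
    """Per-CRM (term, stage) sets via the closest gene, closure applied."""
    parents = parents or {}
    out: dict[str, set[tuple[str, str]]] = {}
    for crm in crms:
        gene = closest_gene(crm, genes)
        terms: set[tuple[str, str]] = set()
        if gene is not None:
            for term, stage in gene_terms.get(gene.gene_id, ()):
                for t in term_closure(term, parents):
                    terms.add((t, stage))
        out[crm.crm_id] = terms
    return out


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 table [[a,b],[c,d]].

    Equals the upper hypergeometric tail P(X >= a) with population
    N = a+b+c+d, K = a+c annotated, n = a+b draws.
    """
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def test_enrichment(conserved_ids: Iterable[str], all_ids: Iterable[str],
                    crm_terms: Mapping[str, set[tuple[str, str]]],
                    min_conserved: int = MIN_CONSERVED,
                    fdr: float = FDR) -> list[EnrichmentResult]:
    """Per-(term, stage) enrichment of conserved CRMs over the background.

    The background is every predicted CRM except the conserved ones.  BH
    is applied jointly across all retained (term, stage) pairs.
    """
    conserved = set(conserved_ids)
    universe = set(all_ids)
    if not conserved <= universe:
        raise ValueError("conserved CRMs must be a subset of all CRMs")
    background = universe - conserved
    pairs: set[tuple[str, str]] = set()
    for cid in universe:
        pairs.update(crm_terms.get(cid, ()))
    rows = []
    for term, stage in sorted(pairs):
        a = sum(1 for cid in conserved if (term, stage) in crm_terms.get(cid, ()))
        if a < min_conserved:
            continue
        c = sum(1 for cid in background if (term, stage) in crm_terms.get(cid, ()))
        b = len(conserved) - a
        d = len(background) - c
        rows.append((term, stage, a, b, c, d, fisher_one_sided(a, b, c, d)))
    if not rows:
        warnings.warn(f"no term reaches {min_conserved} conserved CRMs; "
                      "empty enrichment result")
        return []
    reject, qvals, _, _ = multipletests([r[6] for r in rows], alpha=fdr,
                                        method="fdr_bh")
    results = [EnrichmentResult(term, stage, a, b, c, d, p, float(q), bool(rej))
               for (term, stage, a, b, c, d, p), q, rej
               in zip(rows, qvals, reject)]
    results.sort(key=lambda r: (r.p, r.term, r.stage))
    return results


def write_enrichment_tsv(results: Sequence[EnrichmentResult],
                         path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in results])
    df.to_csv(path, sep="\t", index=False)
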