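"""Ortholog transfer, closest-gene annotation and Fisher/BH testing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from crmscan.crm import CRM
from crmscan.enrichment import (TissueAnnotation, annotate_crms, closest_gene,
                                fisher_one_sided, resolve_orthologs,
                                term_closure, transfer_annotations)
from crmscan.enrichment import test_enrichment as run_enrichment
from crmscan.fixtures import simulate_enrichment_dataset
from crmscan.genes import GeneModel


def crm(start, end, cid="C1", seq="chr1"):
    return CRM(cid, seq, start, end, 10.0, ("M1",), (), 3)


class TestOrthologResolution:
    def test_highest_identity_ortholog_wins(self):
        table = [("zf1", "gA", 80.0), ("zf1", "gB", 60.0), ("zf2", "gC", 50.0)]
        assert resolve_orthologs(table) == {"zf1": "gA", "zf2": "gC"}

    def test_dataframe_input(self):
        df = pd.DataFrame([("zf1", "gA", 55.0), ("zf1", "gB", 90.0)],
                          columns=["zebrafish_gene", "reference_gene",
                                   "pct_identity"])
        assert resolve_orthologs(df) == {"zf1": "gB"}

    def test_transfer_follows_the_resolved_map(self):
        annotations = [TissueAnnotation("zf1", "brain", "st20"),
                       TissueAnnotation("zf9", "somite", "st20")]
        got = transfer_annotations(annotations, {"zf1": "gA"})
        assert got == {"gA": {("brain", "st20")}}


class TestClosestGene:
    GENES = [GeneModel("gA", "chr1", 1000, 2000, "+"),
             GeneModel("gB", "chr1", 100_000, 102_000, "+")]

    def test_distance_is_irrelevant_beyond_choosing_the_flank(self):
        # 1 kb from gA, ~97 kb from gB: gA wins however far away it is
        assert closest_gene(crm(3000, 3100), self.GENES).gene_id == "gA"
        assert closest_gene(crm(99_000, 99_100), self.GENES).gene_id == "gB"

    def test_equidistant_tie_goes_upstream(self):
        mid = (1500 + 101_000) / 2
        c = crm(int(mid) - 50, int(mid) + 50)
        assert closest_gene(c, self.GENES).gene_id == "gA"

    def test_no_gene_on_sequence(self):
        assert closest_gene(crm(0, 10, seq="chrZ"), self.GENES) is None


class TestAnnotateCrms:
    def test_closure_adds_ancestors_with_the_same_stage(self):
        genes = [GeneModel("gA", "chr1", 1000, 2000, "+")]
        gene_terms = {"gA": {("brain", "st20")}}
        parents = {"brain": {"nervous_system"}, "nervous_system": {"anatomy"}}
        got = annotate_crms([crm(3000, 3100)], genes, gene_terms, parents)
        assert got["C1"] == {("brain", "st20"), ("nervous_system", "st20"),
                             ("anatomy", "st20")}

    def test_gene_without_annotation_gives_empty_set(self):
        genes = [GeneModel("gA", "chr1", 1000, 2000, "+")]
        assert annotate_crms([crm(3000, 3100)], genes, {}, {}) == {"C1": set()}

    def test_term_closure_handles_cycles(self):
        parents = {"a": {"b"}, "b": {"a"}}
        assert term_closure("a", parents) == {"a", "b"}


def hypergeom_tail_oracle(a, b, c, d):
    """Upper-tail hypergeometric by explicit log-binomial summation."""
    N, K, n = a + b + c + d, a + c, a + b
    total = 0.0
    for x in range(a, min(K, n) + 1):
        if n - x > N - K:
            continue
        total += math.exp(math.lgamma(K + 1) - math.lgamma(x + 1)
                          - math.lgamma(K - x + 1)
                          + math.lgamma(N - K + 1) - math.lgamma(n - x + 1)
                          - math.lgamma(N - K - n + x + 1)
                          - math.lgamma(N + 1) + math.lgamma(n + 1)
                          + math.lgamma(N - n + 1))
    return min(total, 1.0)


class TestFisher:
    def test_worked_example_against_the_oracle(self):
        p = fisher_one_sided(15, 5, 30, 70)
        assert p == pytest.approx(hypergeom_tail_oracle(15, 5, 30, 70),
                                  rel=1e-10)

    def test_exhaustive_small_tables_match_oracle_and_scipy(self):
        for r1, r2 in itertools.product(range(0, 13, 3), range(0, 13, 3)):
            for a in range(r1 + 1):
                for c in range(r2 + 1):
                    b, d = r1 - a, r2 - c
                    if r1 == 0 or (a + c) == 0:
                        continue
                    p = fisher_one_sided(a, b, c, d)
                    assert p == pytest.approx(
                        hypergeom_tail_oracle(a, b, c, d), rel=1e-9, abs=1e-12)
                    _, p_scipy = fisher_exact([[a, b], [c, d]],
                                              alternative="greater")
                    assert p == pytest.approx(p_scipy, rel=1e-9, abs=1e-12)

    def test_saturated_term_has_no_enrichment(self):
        assert fisher_one_sided(20, 0, 80, 0) == pytest.approx(1.0)


def bh_stepup_oracle(pvals, alpha):
    """Benjamini-Hochberg by its definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_max = 0
    for rank, i in enumerate(order, 1):
        if pvals[i] <= rank * alpha / m:
            k_max = rank
    reject = [False] * m
    for rank, i in enumerate(order, 1):
        if rank <= k_max:
            reject[i] = True
    return reject


class TestBenjaminiHochberg:
    def test_printed_example(self):
        reject = bh_stepup_oracle([0.001, 0.01, 0.02, 0.5], 0.05)
        got, _, _, _ = multipletests([0.001, 0.01, 0.02, 0.5], alpha=0.05,
                                     method="fdr_bh")
        assert list(got) == reject == [True, True, True, False]

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_stepup_definition_on_random_vectors(self, trial):
        rng = np.random.default_rng(9000 + trial)
        m = int(rng.integers(1, 40))
        pvals = np.round(rng.random(m) ** 2, 6)
        got, _, _, _ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        assert list(got) == bh_stepup_oracle(list(pvals), 0.05)

    def test_bh_rejects_at_least_as_much_as_bonferroni(self, rng):
        for _ in range(50):
            m = int(rng.integers(2, 30))
            pvals = rng.random(m) ** 3
            bh, _, _, _ = multipletests(pvals, alpha=0.05, method="fdr_bh")
            bonf = pvals <= 0.05 / m
            assert bh.sum() >= bonf.sum()


class TestTestEnrichment:
    def test_counts_p_and_q_are_consistent(self, rng):
        conserved, all_ids, crm_terms = simulate_enrichment_dataset(rng)
        results = run_enrichment(conserved, all_ids, crm_terms)
        for r in results:
            assert r.a + r.b == len(conserved)
            assert r.a + r.b + r.c + r.d == len(all_ids)
            assert r.a >= 20
            assert r.q >= r.p - 1e-15
            assert r.p == pytest.approx(
                fisher_one_sided(r.a, r.b, r.c, r.d))

    def test_min_conserved_gate(self, rng):
        conserved, all_ids, crm_terms = simulate_enrichment_dataset(
            rng, n_conserved=10)
        with pytest.warns(UserWarning, match="no term"):
            assert run_enrichment(conserved, all_ids, crm_terms,
                                  min_conserved=11) == []

    def test_conserved_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            run_enrichment(["x"], ["y"], {})

    def test_planted_neuronal_signal_detected_nonneuronal_quiet(self):
        """Neuronal terms (2x frequency) reach FDR significance in >=95% of
        simulations; at-parity terms stay quiet in >=95% per term."""
        rng = np.random.default_rng(0)
        neuronal = {"brain": 0, "spinal_cord": 0, "nervous_system": 0}
        nonneuronal = {"pronephros": 0, "somite": 0}
        n_sims = 100
        for _ in range(n_sims):
            conserved, all_ids, crm_terms = simulate_enrichment_dataset(rng)
            significant = {r.term for r in
                           run_enrichment(conserved, all_ids, crm_terms)
                           if r.significant}
            for term in neuronal:
                neuronal[term] += term in significant
            for term in nonneuronal:
                nonneuronal[term] += term in significant
        for term, count in neuronal.items():
            assert count >= 0.95 * n_sims, term
        for term, count in nonneuronal.items():
            assert count <= 0.05 * n_sims, term
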