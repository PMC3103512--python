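"""Filter CRMs by conservation to human and rank the candidates.

Each CRM is anchored on the closest reference gene with a human ortholog
and locally aligned (HOXD70 matrix, affine gaps 400/30 — the BLASTZ
scoring scale) to the neighbourhood spanned by the ortholog and its
flanking genes.  A CRM passes with score > 2600 AND identity > 60%, both
strict.  Passing CRMs are ranked by CRM score: the top 10 plus 10 spread
through the top 200 at fixed rank positions.
"""

from crmscan import (align_to_human, anchor, call_crms, conserve_hits,
                     fixtures, scan_all, select_candidates)

bundle = fixtures.generate()
hits = scan_all(bundle.ref_records.values(), bundle.pwms)
conserved = conserve_hits(hits, {p.matrix_id: p for p in bundle.pwms},
                          bundle.blocks, bundle.species_records)
crms = call_crms(conserved)

scored = []
for c in crms:
    a = anchor(c, bundle.genes, bundle.human_orthologs, bundle.human_genes)
    human = bundle.human_records[a.search_seq_id]
    search = human.sequence[a.search_start:min(a.search_end, len(human))]
    crm_seq = bundle.ref_records[c.seq_id].sequence[c.start:c.end]
    call = align_to_human(c.crm_id, crm_seq, search)
    scored.append((c, call))
    flag = "PASS" if call.passes else "    "
    print(f"{flag} {c.crm_id} via {a.ref_gene}->{a.human_ortholog}: "
          f"score {call.aln_score:6.0f}, identity {call.pct_identity:5.1f}%")

import warnings
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # fewer than 200 passing at fixture scale
    selection = select_candidates(scored)
print("top candidates:", [c.crm_id for c in selection["top10"]])
# At genome scale spread10 holds the CRMs at ranks 20, 40, ..., 200; on a
# small dataset the positions clip to what exists.
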