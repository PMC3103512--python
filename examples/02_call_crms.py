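"""Cluster conserved hits into CRMs and build fused test regions.

Windows of up to 1 kb holding at least 3 conserved hits are scored (best
hit per matrix for up to 5 distinct matrices; top-5 hits for homotypic
clusters) and the best non-overlapping windows become CRMs.  Close-by CRMs
are then fused and extended by 200 bp flanks into regions one would clone
for an enhancer assay.
"""

from crmscan import (call_crms, conserve_hits, fixtures, fuse_and_extend,
                     scan_all, summarize)
from crmscan.fixtures import evaluate_recovery

bundle = fixtures.generate()
hits = scan_all(bundle.ref_records.values(), bundle.pwms)
conserved = conserve_hits(hits, {p.matrix_id: p for p in bundle.pwms},
                          bundle.blocks, bundle.species_records)
crms = call_crms(conserved)

stats = summarize(crms)
print(f"{stats['count']} CRMs called "
      f"(mean length {stats['mean_length']:.0f} bp, median "
      f"{stats['median_length']:.0f} bp, {stats['mean_sites']:.1f} "
      "conserved sites each)")
for c in crms[:3]:
    print(f"  {c.crm_id} {c.seq_id}:{c.start}-{c.end} "
          f"score {c.score:.1f} bits, tag matrices {','.join(c.tag_matrices)}")

regions = fuse_and_extend(crms, bundle.seq_lengths)
print(f"{len(regions)} test regions after fusing gaps <= 500 bp and "
      "adding 200 bp flanks")

metrics = evaluate_recovery(crms, bundle.planted)
print(f"against the planted ground truth: recall {metrics['recall']:.2f}, "
      f"precision {metrics['precision']:.2f}")
# Recall counts planted clusters overlapped by a call; precision counts
# calls that land on a planted cluster.
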