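"""Where do CRMs sit relative to genes, and is that placement biased?

CRM midpoints are binned by distance to the nearest TSS and classified
intragenic/intergenic; the observed fractions are compared with 100
randomizations placing the same number of same-length intervals uniformly
in unmasked sequence.  Empirical p uses (r+1)/101, so r=0 gives the floor
p = 1/101 < 0.01.
"""

from crmscan import (call_crms, conserve_hits, fixtures, randomize_and_test,
                     scan_all)

bundle = fixtures.generate()
hits = scan_all(bundle.ref_records.values(), bundle.pwms)
conserved = conserve_hits(hits, {p.matrix_id: p for p in bundle.pwms},
                          bundle.blocks, bundle.species_records)
crms = call_crms(conserved)

result = randomize_and_test(crms, bundle.genes, bundle.seq_lengths,
                            masks=bundle.masks, n_rand=100, seed=0)
print(f"{result.observed.n} CRMs classified")
print("TSS distance bins (fraction of CRMs / empirical p):")
for name, frac in result.observed.tss_bins.items():
    print(f"  {name:>9}: {frac:5.2f}   p({result.direction[name]}) = "
          f"{result.empirical_p[name]:.3f}")
print("gene classes:")
for name, frac in result.observed.gene_classes.items():
    print(f"  {name:>16}: {frac:5.2f}   p({result.direction[name]}) = "
          f"{result.empirical_p[name]:.3f}")
# The fixture plants CRMs intergenic near genes, so intergenic and
# near-TSS categories deviate from the random null; p = 0.010 means the
# observed fraction beat all 100 randomizations.
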