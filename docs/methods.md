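# Methods

This note documents the models, parameter choices and numerical
conventions behind `crmscan`, and what the synthetic datasets do and do
not establish about behaviour on real genomes.

## Binding-site model and scanning

A PWM is stored as a width × 4 base-probability table. Count or frequency
matrices are normalized per position, then a pseudocount of 0.01 is added
to each cell and the row renormalized, guaranteeing strictly positive
probabilities and finite log-odds. Scores are bits against a uniform
background: `s(i, b) = log₂(p(i, b) / 0.25)`; the maximum achievable
score is the sum of per-position row maxima. The uniform background (as
opposed to a local-GC model) makes scores comparable across the genome
and across matrices at the cost of some sensitivity in GC-skewed regions.

Both strands are scanned; the reverse strand is scored by applying the
reverse-complemented matrix to the forward sequence, which is identical
to scoring the reverse complement of each window. Windows containing a
masked position (lower-case repeat, annotated coding sequence) or a
non-ACGT letter are skipped entirely. The per-matrix hit threshold is a
fraction of the maximum achievable score, default 0.75. The fraction is
deliberately permissive: individual hits are not the selective step —
CRM-level scoring is — so the scanner's job is to not lose sites that
clustering could rescue. Overlapping hits of one matrix are all kept;
deduplication happens implicitly at CRM scoring, which counts at most the
top-K sites.

Matrix curation follows the conventions of pooled TRANSFAC/JASPAR
collections: non-vertebrate entries are dropped (the factor species is
read from TRANSFAC BF lines; a configurable allow-list retains selected
invertebrate matrices for factors with vertebrate developmental roles,
since the historically retained set is not enumerable from metadata),
matrices linked to more than two factors of one species are discarded as
promiscuous, and one matrix per factor is kept by best quality code
(A < B < …; quality parsed from the matrix name suffix).

## Conservation weighting

Each reference hit is projected through pairwise alignment blocks (MAF or
a TSV cigar dialect; the per-base offset map must be monotone, so only
forward-strand comparison rows are representable) into each comparison
genome, and the projected window ± 20 bp is rescanned with the same
matrix on both strands. The combined score is

    combined = ref + max over species of max(0, support − λ·|offset|)

with absent species contributing zero. The misalignment penalty is
linear, λ = 0.1 bits/bp, floored at zero; λ = 0 recovers pure
eligibility-within-20-bp semantics, and the default makes a 20 bp
misalignment cost 2 bits — noticeable but not disqualifying for a strong
site. Support in either orientation counts, since binding-site
orientation is symmetric under local inversion. The supporting species
reported on ties is the first of (tetraodon, stickleback, fugu) for
reproducibility; the score itself is orientation- and tie-independent.
Rescanning the projected window (rather than intersecting precomputed
per-genome hit lists) gives identical results by construction and keeps
the contract simpler.

## CRM calling

Each conserved hit anchors a candidate window covering the hits starting
within 1 kb of it. A window needs ≥ 3 conserved hits. Its score is the
sum over *contributing* hits: for oligotypic windows the best hit of each
of the top-5 distinct matrices; for homotypic windows (one matrix) the
top-5 hits of that matrix, so single-factor clusters are not starved to
one site. Candidates with score ≥ 45 bits enter greedy selection by
descending score (leftmost wins ties); candidates overlapping an accepted
CRM are discarded. CRM boundaries are trimmed to the outermost
contributing hits, so the stored score always re-derives exactly as the
sum of the stored hits' combined scores; `n_sites` counts every conserved
hit inside the trimmed span.

The 45-bit default is chosen so that a qualifying cluster must carry
conservation support: three unconserved hits at the default per-matrix
threshold contribute ≈ 3 × 14 = 42 bits for the synthetic matrix set, just
under the cutoff, while a cluster with even modest cross-species support
clears it easily. A quantile-based calibration against a shuffled-hit
null (`calibrate_score_threshold`, 99th percentile of null candidate
scores) is provided for genome-scale hit sets, where the shuffle null is
meaningful; on desk-scale data that null is dominated by displaced
planted hits and over-shoots, which is why the default is set by the
support argument instead.

CRMs separated by ≤ 500 bp are fused, and fused regions gain 200 bp
flanks (clipped at sequence ends) to form the regions one would amplify
for an enhancer assay.

## Vertebrate-conservation filter

The CRM's closest reference gene with a human ortholog anchors the
search: the human interval spanned by the ortholog and its flanking genes
(± 10 kb padding) is the target of a Smith–Waterman local alignment under
the HOXD70 substitution matrix with affine gap costs 400 (open) + 30 per
base — the scoring scheme of BLASTZ, so the published score scale
applies directly. Both query strands are tried. Percent identity is
matches over aligned columns (gaps included) of the best local alignment.
A CRM passes with score > 2600 AND identity > 60%, both strictly: a score
of exactly 2600 or identity of exactly 60 fails. Passing CRMs are ranked
by CRM score, ties broken by genomic position; the candidate lists are
ranks 1–10 and the fixed rank positions (20, 40, 60, 81, 100, 120, 140,
159, 180, 200), the latter taken verbatim as given rather than
regularized to multiples of 20.

## Genomic location and the randomization null

CRMs are represented by their midpoints, which avoids length-induced
bias. Distance to the nearest TSS is binned half-open into < 1 kb,
1–10 kb, 10–100 kb, > 100 kb; a midpoint inside any gene span is
intragenic, otherwise intergenic, split at 100 kb from the nearest gene
*boundary* (boundary, not TSS, is the convention chosen for the
intergenic split; the TSS bins capture promoter proximity separately).
The null places the same number of intervals, with the observed length
multiset (permuted), uniformly in unmasked sequence — matching the
domain the predictor actually scans — and repeats 100 times. Empirical
p-values use the add-one rule (r+1)/(n_rand+1) counting null values as or
more extreme, so p = 1/101 (< 0.01) corresponds to an observation beyond
all 100 randomizations and p = 0 is impossible. The reported one-sided p
takes the direction of the observed deviation.

Because the classified fractions are discrete, the as-or-more-extreme
rule counts ties fully and the reported p is conservative
(super-uniform) under the null by construction. `RandomizationResult`
therefore also carries `p_mid_greater`, the standard mid-p variant (ties
count half), which is uniform under the null and is the quantity checked
by the calibration tests. Calibration uses 100 intervals per simulated
dataset: tie mass shrinks roughly with 1/√n, and at 100 intervals the
KS uniformity check probes the statistic rather than the discreteness.

## Enrichment testing

Zebrafish annotations transfer to reference genes through the
highest-identity ortholog (one reference gene per zebrafish gene). Each
CRM inherits the annotation of the closest of its two flanking genes by
midpoint distance — distance is otherwise irrelevant, and ties go to the
upstream gene. Ontology closure is applied through an explicit
child → parent table (optionally read from OBO `is_a`/`part_of` edges), so
a subpart annotation counts for the enclosing tissue at the same stage.
Terms carried by ≥ 20 vertebrate-conserved CRMs are tested: conserved vs
all-other-predicted CRMs × annotated vs not, one-sided Fisher exact test
in the enrichment direction, computed as the upper hypergeometric tail.
Benjamini–Hochberg control at 5% FDR is applied jointly across all
retained (term, stage) pairs — the conservative reading of per-term
versus joint control.

## Assay quality control

`n_lens / n_alive` is the injection success rate (lens expression is the
minimal promoter's intrinsic readout); `n_specific / n_lens` the
reproducible-pattern rate. Positive requires strictly more than 0.5 AND
at least 10 fish. Rare non-consistent expression (enhancer-trap-like,
about 1 in 50 embryos) is expected to be excluded from `n_specific`
upstream during annotation. Ontology coverage reports
`floor(100 · labeled / vocabulary)` — the floor convention makes 20 of 32
print as 62. Rates are pooled per region across injection batches.

## Synthetic datasets

The generator emulates every input the pipeline consumes, at desk scale,
from one seed (byte-identical bundles per seed): two 50 kb reference
sequences at GC 0.40 with ~8 genes each; 10 planted CRMs of 8 consensus
sites (per-base mutation rate ε = 0.05, a rate at which one-mismatch
sites still clear the default threshold) centred in the widest intergenic
gaps, three of them mixing two matrices; three comparison genomes at 30%
neutral divergence carrying the planted sites at per-CRM offsets ≤ 12 bp
with 5% extra divergence; full-length identity alignment blocks (MAF and
TSV); per-gene human neighbourhood sequences in which the 6
"high-identity" planted CRMs are embedded at 85% identity — in the
neighbourhoods of both flanking genes, mirroring the fact that adjacent
genes' genomic neighbourhoods overlap; ortholog tables (including
deliberate multi-ortholog rows to exercise resolution); tissue
annotations with neuronal terms at 0.6 frequency near human-conserved
CRMs versus 0.3 background and non-neuronal terms at parity; and an
injection table with 19 of 20 regions positive.

What the fixtures do not emulate: realistic neutral evolution (no
phylogeny, no indels in the comparison genomes outside the alignment
dialect tests), genome-scale hit densities (hundreds of matrices produce
orders of magnitude more background hits than six), repeat families,
or the ZFIN annotation corpus. Passing tests therefore establish the
correctness of the algorithms and their wiring, and qualitative behaviour
(planted-cluster recovery, direction of location bias, enrichment
detection at 2× frequency), not genome-scale operating characteristics
such as the published CRM counts or length distributions. At 30%
comparison-genome divergence a background hit still has a ~15% chance of
retaining spurious support, so occasional background clusters can pass
the CRM threshold on some seeds — visible as planted-CRM precision
slightly below 1.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open everywhere; GFF3 converts at the
boundary. Empty hit lists, empty screens and termless CRMs are valid
inputs yielding empty outputs (with warnings where silence would
mislead). The enrichment table with no retained terms is an empty result,
not an error. Score round-trips through BED store centibits (bits × 100,
rounded). All randomness flows from explicit seeds or
`numpy.random.Generator` instances; pipeline runs are bit-reproducible
given config and seed, and the run manifest records input/output SHA-256
hashes and the full parameter set. Problem sizes in tests and in the
acceptance script (two 50 kb sequences, 200 calibration datasets of 100
intervals, Fisher tables with margins ≤ 50) are chosen as the smallest
sizes at which each property is statistically meaningful.
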