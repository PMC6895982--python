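# Methods

This note documents the models, conventions and numerical choices behind
`homeobias`, and what the synthetic-data generator does and does not
emulate.

## System and assumptions

The package models a single nuclear gene in an allopolyploid (genome HHCC)
formed from a maternal diploid (HH) and a paternal diploid (CC). Assumed
throughout:

- each diploid parent is homozygous at the gene (one ortholog per parent),
  and the polyploid carries one homoeolog per subgenome;
- the polyploid C-type homoeolog may be identical to the paternal ortholog,
  while the H-type homoeolog may have accumulated post-polyploidization
  mutations; both cases are handled, and the H/C labels come from the
  caller's role assignment, not from sequence similarity;
- divergence between orthologs is small (≈ 95 % identity or higher), so a
  single deterministic global alignment is an adequate statement of
  homology — no paralogy, no rearrangements, no alternative splicing.

## Alignment and variant calling

Global (end-to-end) pairwise alignment with affine gap penalties, scored
match +2, mismatch −3, and a gap of length L costing 6 + L. These values
resolve the placement of isolated substitutions and short indels
unambiguously at the identity levels above: a single mismatch (−3) is
always preferred to a pair of compensating gaps (≥ −14). The engine is
Biopython's `PairwiseAligner`; among co-optimal alignments the first
deterministic traceback is used, so variant coordinates are reproducible
run to run. Scoring is configurable (`Scoring`).

Variant conventions:

- every mismatching non-gap column is one SNP; columns containing N are not
  called;
- every maximal gap run is one indel, anchored to the last aligned base
  before the run on the ungapped sequence (VCF-style left anchoring);
- regions (`exon k` / `intron k`) are assigned from the reference
  sequence's exon intervals; all reported coordinates are 1-based
  inclusive;
- coding effects translate the codon containing the site in each sequence
  with the standard genetic code (synonymous iff the residues agree);
  codons containing N, incomplete codons, and codons disrupted by an
  alignment gap are `not_applicable`;
- amino-acid differences are counted through the nucleotide alignment:
  residues whose codons co-align (≥ 2 of 3 bases) are compared directly,
  and a residue aligned to a gap counts as one difference — a deliberately
  conservative choice, documented because gap handling changes the count.

## Diagnostic homoeo-SNPs

A site is *diagnostic* when the parents differ, the polyploid H copy
carries the maternal allele, the polyploid C copy carries the paternal
allele, and the site is exonic (mappable to cDNA, where reads are counted).
A density filter then clears the `retained` flag of any diagnostic SNP
whose nearest neighbouring called SNP is ≤ 5 bp away in cDNA coordinates
(strictly greater distances are retained). The filter mirrors the practice
of discarding clustered SNP calls from read mappings, where nearby variants
make allele observations unreliable; cDNA rather than genomic distance is
used because the reads are mapped to cDNA. Cross-sequence homology is
always resolved through pairwise alignments anchored on the maternal (or
own-parent) coordinate system — an anchored three/four-way construction,
not a full multiple alignment, which is adequate at single-gene scale.

Post-polyploidization mutations of a homoeolog relative to its own parent
are labelled *directional* when the new base equals the other parent's
allele at the homologous position (convergent), otherwise
*non-directional*; positions falling in an alignment gap of the other
parent are non-directional with a gap flag.

Clone filtering: a distinct sequence from cloned PCR products is accepted
as a true gene copy iff its support fraction is ≥ threshold (default 0.25)
in **every** independent PCR experiment; the boundary is closed, so support
of exactly 25 % passes.

## Read counting

Reads are assigned per SNP: a read overlapping a retained diagnostic
position increments the maternal count if its base matches the maternal
allele, the paternal count for the paternal allele, `other` for a third
allele, and `low_quality` below the base-quality cutoff (default Q20; the
study's own filters are unstated, so the default is configurable and
synthetic reads are Q40 to keep it inert unless exercised). `Total` is
maternal + paternal only — third-allele and low-quality observations never
enter the bias test. Mates sharing a read id are collapsed so each fragment
counts once per SNP; a read spanning two SNPs contributes to both columns
independently, matching the per-SNP shape of the count table. SAM input
(via pysam) skips secondary/supplementary records and soft-clipped bases.

The built-in FASTQ aligner places reads by exact k-mer anchor (default
k = 15, both orientations) with ungapped extension, keeping the placement
with fewest mismatches (ties: forward strand, then leftmost) and dropping
reads above 20 % mismatches. It is intended for single-gene references at
simulation scale; real libraries mapped with a production mapper can be
supplied as SAM instead.

FPKM = fragments × 10⁹ / (transcript length in bp × library fragments).

## Statistics

**Bias test.** Under the null, each informative read carries either
parental allele with probability p₀ = 0.5. The two-sided p-value of counts
(h, c) sums P(X = k) over all k whose point probability does not exceed
that of the observed count (X ~ Binomial(h + c, p₀)) — the
minimum-likelihood convention of R's `binom.test`, stated explicitly
because competing two-sided definitions exist. Point probabilities within a
1 + 10⁻⁷ relative band of the observed one count as ties, again following
that convention. No normal approximation is used at any total. Across the
(replicate × SNP) family, Benjamini–Hochberg adjusted p-values are reported
alongside the raw ones; raw p-values remain the primary output since the
family is small and the per-replicate claims are marginal. Pooled
per-replicate tests sum counts over SNPs.

**2^−ΔΔCt.** ΔCt = target Ct − arithmetic mean of the reference-gene Cts;
averaging in Ct (log₂ quantity) space is exactly normalization to the
geometric mean of the reference quantities. Relative expression is
2^−(ΔCt_sample − ΔCt_calibrator). Sample and calibrator must share the same
reference-gene set; the result is invariant to any constant shift applied
to every Ct.

**Mid-parent heterosis.** MPH% = (polyploid mean − mid-parent mean) /
mid-parent mean × 100, with the mid-parent mean the unweighted average of
the two parental genotype means. Genotype means are reported with
SE = sd/√n (sample sd, n − 1 denominator; SE is undefined for n = 1). MPH
is reported to 2 decimals and is undefined when the mid-parent mean is 0.

## Synthetic data

The generator plants, per seed: an ~850 bp gene (three exons, two introns,
complete CDS with no internal stops, 633 bp of cDNA); 33 parental SNPs of
which 8 intronic; 3 intron-restricted indels (1–5 bp, placed so the
left-anchored position is unambiguous); a polyploid C allele identical to
the paternal sequence and an H allele with 12 directional + 8
non-directional mutations; single-end 100 bp reads with per-base error rate
ε = 0.005 at paternal fraction θ = 0.58 over 3 replicates; and
qPCR/trait/clone fixtures. One global seed fans out to four independent
substreams (parents, polyploid, reads, tables) via `SeedSequence.spawn`, so
stages regenerate independently and identically.

Two diagnostic-site choices deserve note:

- Exactly two exonic SNP sites are reserved as retained diagnostic SNPs;
  all other exonic parental SNPs are planted in clusters tighter than the
  5 bp density filter, so the filter removes them — reproducing the
  situation where many homoeo-SNPs exist but only a couple survive
  filtering. The reserved sites are placed ≥ 200 cDNA bp apart (the filter
  only requires them isolated by > 5 bp); with 100 bp reads this keeps the
  two sites' read sets disjoint, so pooled counts carry independent
  information.
- `depth` (default 1500) is the expected number of reads *overlapping each
  diagnostic site* per replicate — the per-SNP count-table total, which is
  the quantity such studies report — and the library size is derived from
  it (≈ 8000 reads per replicate for the default geometry).

Trait fixtures draw Gaussian replicates around genotype means chosen to hit
each trait's target MPH (defaults: content 1.41/1.77 with target 6.90 %,
activity 7.24/4.76 with target 14.32 %, matching the scale of the real
measurements).

What the generator does **not** emulate: paired-end fragments and insert
sizes, position- or motif-dependent error profiles, quality-score
distributions (all bases are Q40), expression differences between
replicates beyond binomial sampling, PCR duplicates, and mapping ambiguity
from gene families. Passing tests therefore demonstrate correctness of the
counting and inference machinery under clean single-gene conditions, not
robustness to every artefact of real libraries — for real data the SAM
ingestion path with an external mapper is the supported route.

## Problem sizes used in the checks

The calibration checks run the bias test on 1000 simulated count pairs at
depth 1000 (null, θ = 0.5) and depth 1500 (θ = 0.58), and the end-to-end
recovery check runs 20 full simulations at the default configuration —
sizes chosen to make binomial sampling error small relative to the margins
being asserted while keeping the whole suite fast on a laptop.

## Known limitations

- One gene, one diagnostic-SNP scale: no genome-wide data structures.
- The anchored multi-way construction assumes the polyploid copies align
  cleanly to their parents; highly rearranged copies would need a real MSA.
- The exact binomial test treats reads as independent draws; fragments
  covering two SNPs are counted in both columns (per-SNP reporting), so
  pooled-over-SNP tests can double-count such fragments when sites are
  < 1 read length apart. The generator's default geometry avoids this; for
  real data with adjacent SNPs, prefer the per-SNP tests.
- Duncan-type multiple-range post-hoc tests and protein binding-affinity
  prediction are out of scope.
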