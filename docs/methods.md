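# Methods

This note documents the models, decision rules and numerical choices
behind `syntloss`, and what the synthetic fixture does and does not
establish about behavior on real data.

## Ortholog anchoring

Anchor pairs are reciprocal best hits (RBH) over Smith–Waterman local
protein alignments (BLOSUM62; affine gaps costing `gap_open +
(L−1)·gap_extend`, defaults 11/1, the convention of Biopython's
`PairwiseAligner`, which performs the alignments).  A pair (r, q) is an
anchor iff q is r's *unique* highest-scoring hit and vice versa, with
alignment identity ≥ 0.3 and min(coverage) ≥ 0.5.  Score ties drop the
gene entirely: ambiguous orthology must not seed synteny.  Identity is
matches over gapless aligned columns; coverage is aligned span over
sequence length.  An all-vs-all alignment is avoided by a shared-5-mer
prefilter (≥ 2 shared peptide 5-mers, the usual seeding idea;
`prefilter_k=None` disables it).  Full Markov-cluster orthology is out
of scope — the loss pipeline needs only 1:1 anchors.

## Synteny chaining

Within each (reference scaffold, query scaffold) pair, the
maximum-score collinear chain over anchors is found by an O(n²) dynamic
program, separately for the two orientations: anchor j may follow i
when both per-genome rank gaps (skipped genes) are ≤ `max_gap`
(default 10) and the query ranks run monotonically in the chain's
orientation.  Chain score = Σ anchor scores − `gap_penalty` (default
1.0) per skipped rank on either genome.  Blocks are extracted greedily
(best chain, remove its anchors, repeat); chains with fewer than
`min_block_size` (default 4) anchors are discarded; ties prefer the
smaller starting rank, making output deterministic.  The DP is verified
against exhaustive enumeration over all collinear anchor subsets on
random instances.

The flanking window of a reference gene takes up to `w` = 5 anchors on
*each* side (the published rule names "five syntenic gene pairs" without
saying per-side or total; per-side is the symmetric choice and is
configurable), spans their query gene intervals, and extends by a
2,000 bp margin clipped to the scaffold.

## Loss candidates and the four filters

A non-anchor reference gene whose rank lies strictly inside a block's
anchor span becomes a candidate iff no annotated query gene overlapping
its window aligns to its protein at identity ≥ 0.5 and coverage ≥ 0.5
(a deliberately permissive screen: any plausible in-window homolog
suppresses the candidate; the published thresholds apply to the rescue
step, where they matter).

Filters run in a fixed order and the first rescue wins:

1. **Unanchored rescue.**  Six-frame translated local alignment of the
   reference protein against every unanchored scaffold (identified by ID
   prefix, default `scaffold_un_`).  Rescue at identity ≥ 0.80 and
   protein coverage ≥ 0.80.
2. **Missannotation rescue.**  The same search against the candidate's
   window DNA.  Splice-aware re-annotation is replaced by translated
   alignment: since one affine gap bridges an intron inside a single
   frame's translation, a hit can span several exons; the 0.80/0.80
   decision rule — the part that matters — is preserved exactly.
3. **Read-depth validation.**  Query reads are mapped to the reference
   genome; the candidate supports loss only if gene-body mean depth
   < 1× **and** covered fraction < 5%, both strict ("depth" is read as
   mean over the body; the two criteria are conjoined as published).
   Otherwise the candidate is rescued by read evidence.
4. **Residue inspection.**  Best local hit per (strand, frame) of the
   window, chained by protein coordinate (overlaps ≤ 30 aa tolerated,
   because local alignments overrun a frameshift junction by chance
   matches).  Reported: overall identity, premature stops (stop codons
   aligned against reference residues; in-frame intron stops fall in
   gap columns and are not counted), frameshifts (frame changes between
   chained hits), and the longest run of consecutive identical
   residues.  A run ≥ `min_conserved_run` (default 10 aa) labels the
   locus pseudogenized rather than absent.

### The pseudo-mapper

The depth track comes from a minimal seed-and-extend mapper: exact
match of the read's first 31 bases (both strands) against a genome
index, ungapped full-length extension, acceptance iff total mismatch
fraction ≤ 0.10, reads with multiple equally good placements discarded.
Depth is deposited over the read's maximal-scoring contiguous segment
(+1 match / −3 mismatch), i.e. diverged tails are soft-clipped as a
local mapper would.  With cross-species reads at ~5% divergence the
31-mer exact seed passes ≈ 0.95³¹ ≈ 21% of reads — plenty for a
presence/absence criterion, and loci diverged at ≥ 25% receive
essentially no reads, which is the behavior the depth filter relies on.
A precomputed BED-like depth track can be supplied instead.

## Rate tests

**Tajima's relative rate test.**  Over gap-free columns of a (focal,
reference, outgroup) triplet: m₁ = sites where only the focal species
differs (focal ≠ reference, reference = outgroup), m₂ symmetric for the
reference; columns where all three states differ count for neither.
χ² = (m₁−m₂)²/(m₁+m₂) with 1 df (χ²=0, p=1 when m₁+m₂=0).  Under a
clock the empirical type-I error at α=0.05 is ≈ 5% (measured 5.7% over
2,000 simulated replicates of 10,000 sites — the χ² approximation is
slightly anticonservative at finite counts).

**Two-cluster test.**  Δ = mean outgroup distance of cluster A − that
of cluster B, distances JC69 by default (d = −¾ ln(1−4p/3), undefined
at p ≥ 0.75 → error naming the pair), complete deletion across all
involved species.  The standard error comes from B = 1,000 seeded
column-bootstrap replicates (the reference implementation's analytic
variance is not published; the bootstrap is transparent and testable),
Z = Δ/SE referred to the standard normal, two-sided.  Swapping clusters
negates Δ and Z exactly.

## Genome survey and summary arithmetic

K-mers (k odd, default 17) are counted canonically (lexicographic
minimum of k-mer and reverse complement); k-mers containing N are
skipped.  The error trough is the first depth at which the dense
histogram rises; the peak is the argmax above it.  Genome size =
occurrence-weighted k-mer total divided by the coverage-peak depth.
When the division starts from a quoted total and peak
(`SurveyEstimate.from_counts`) it is exact integer arithmetic, rounded
half away from zero.  When estimated from a histogram, the divisor is
the count-weighted mean depth above the trough rather than the raw
argmax: on finite surveys adjacent genomic k-mers share covering reads,
so histogram counts carry block-correlated noise and the flat peak's
argmax jitters by ±1–2 depth units (alone worth ~5–10% of the
estimate), while the weighted mean is the survey's k-mer coverage rate
and is stable to < 0.1% on clean simulations.  Heterozygosity and
repeat-fraction model fitting are out of scope.

Nxx statistics use the descending-cumulative definition with exact
integer thresholds (`cum·100 ≥ xx·total`); percentages round half away
from zero to two decimals.

## The synthetic fixture

One ancestral sequence is mutated into both species (half the
configured divergence per branch, i.i.d. uniform substitutions; codons
that would become stops revert, so annotated proteins stay valid).
Base composition is uniform and intergenic spacers are unrealistic on
purpose: the filters respond to homology/coverage structure, not
composition.  Genes are exon/intron structures with introns fixed at
81 bp — a multiple of 3, so all exons of a locus share a reading frame
and the translated-search filters need no splice model.  Defaults: 200
genes on 4 scaffolds, CDS ≈ 900 bp (2–4 exons), background divergence
0.05, read coverage 20× at 100 bp, error rate 0.001, two 8-gene
inversions (gene-order reversals).

Planted events, assigned to well-separated interior genes:

* **true deletion** — the full genomic span is removed;
* **pseudogenization** — the query branch diverges at 0.25
  substitutions/site (chosen so cross-species read mapping fails at the
  locus), with one planted in-frame stop, one 1-bp frameshift deletion,
  and a 30-codon window *synonymously recoded* from the reference CDS:
  protein residues conserved (the recognizable-residue signal for
  filter 4) while the DNA stays diverged (so filter 3 still supports
  loss).  The annotation is dropped;
* **annotation dropout** — intact locus, annotation dropped;
* **moved to unanchored** — the locus is removed and an intact,
  *unannotated* copy appended on a `scaffold_un_*` scaffold (unplaced
  scaffolds are typically unannotated; this also keeps RBH anchors
  exactly the retained 1:1 pairs).

Under the default configuration the pipeline classifies all 20 planted
events correctly (8 absent, 4 pseudogenized, 4 missannotation rescues,
4 unanchored rescues) with zero false calls among the 180 retained
genes.

What this does *not* show: performance under realistic indel/repeat
landscapes, heterozygosity, paralogy, splice-site evolution, or genes
far longer/shorter than ~1 kb.  One measured sensitivity: because
fixture genes are ~1 kb, the strict 5% body-coverage rule equals about
one read's span, and a pseudogene that by chance retains a ~50 bp
stretch of ≥ 85% DNA identity adjacent to conserved flanking sequence
can attract a single read and be (conservatively) rescued as having
read evidence — observed once across ten simulation seeds.  On real
multi-kilobase genes the same absolute creep is far below 5%.

## Determinism

Every stochastic step takes an explicit seed and routes all sampling
through one `numpy` generator per call; re-running any stage or the
whole pipeline with an identical configuration reproduces byte-identical
output files (the run manifest records SHA-256 digests to make this
checkable).
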