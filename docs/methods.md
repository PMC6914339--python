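# Methods

This note documents the models, conventions and parameter choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user may want to override.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open; GFF3 is converted at the
I/O boundary (1-based closed → half-open) and converted back on writing.
Touching intervals do not overlap. Interval sets iterate in a fixed order
(chromosome, start, end, name) so that every derived output is reproducible
across runs. Overlap queries use merged per-chromosome coordinate arrays
and binary search; correctness is checked against quadratic all-vs-all
scans in the test suite.

## Binding sites, annotation, targets

A binding site is a region supported by both ChIP replicates. Of the
possible readings of "common peak region" (intersection, union,
replicate-1-anchored), the intersection of each overlapping replicate-1 ×
replicate-2 pair is used — the conservative choice — and overlapping
intersections are merged. Per-replicate reproducibility is the fraction of
a replicate's peaks overlapping the other replicate.

Sites are annotated to the gene whose TSS minimises the absolute signed
distance from the site midpoint, measured in the gene's orientation
(negative = upstream). The midpoint anchor makes the distance well defined
for sites of any width. Feature classes: *promoter* when the midpoint lies
within `promoter_span` (default 3000 bp) upstream of the TSS, *gene body*
when it falls inside the nearest gene's span, *intergenic* otherwise.
Target genes are sites with distance in the inclusive window
[−1500, +500] bp; both boundaries are inclusive, a one-base convention the
user can shift by passing different window arguments.

## Motif model

The default motif is the canonical CArG-box consensus CC(A/T)6GG. Because
each consensus position constrains a base set independently, the minimal
Hamming distance from a 10-mer to the 2^6-word motif class equals the
count of positions violating their base set; this is what the scanner
computes, vectorised, on both strands (the reverse-complement reading uses
the complemented, reversed consensus). Distance 0 is *perfect*, distance 1
*nearly perfect* (one substitution away from some perfect word). `N`
counts as a mismatch wherever it appears. The CArG consensus class is its
own reverse complement, so every occurrence matches on both strands; such
double hits are collapsed to a single record (forward strand reported).
Overlapping occurrences are all reported, and densities count occurrences
per base of a region class, not merged footprints. Chi-square tests on
motif-base versus non-motif-base counts are computed without Yates
correction by default (flag available). Position weight matrices can be
supplied for motifs exported from a discovery tool; the consensus scanner
is the default because the published motif is a consensus.

## TE-overlap permutation test

The null model preserves the observed site count and length multiset.
Each random site is placed in a promoter drawn uniformly among the
promoters long enough to contain it, then uniformly within that promoter
(containment enforced; a length-weighted promoter choice is available as
an option). The promoter universe is the 3-kb upstream span of every gene,
unclipped by neighbouring features by default. One sequence of `n_iter`
random site sets (default 10,000) is scored against every TE superfamily,
mirroring the use of a single random control set. The empirical p-value
uses the add-one rule (r + 1)/(n_iter + 1), which never returns zero; the
z-score is (observed − null mean)/null s.d., reported as NaN when the null
distribution is degenerate. Calibration on null data (sites independent of
TEs) is part of the test suite: the α = 0.05 rejection rate over 200
simulated datasets must fall in the binomial 99% band and the p-values
must pass a KS uniformity check. Because the overlap fraction is discrete,
the calibration universe uses enough sites (500) and TE copies that the
p-value distribution is effectively continuous.

## Homology of motif-carrying TEs

Pairs of motif-carrying TE sequences are compared by optimal local
alignment under BLASTN-style scoring: match +2, mismatch −3, affine gap
cost 5 + 2k for a length-k gap. The alignment engine is exhaustive
Smith–Waterman dynamic programming (Biopython's PairwiseAligner) rather
than a seeded word heuristic: at desk scale the exact optimum is
affordable, can only find more homologies than seeding, and leaves the
biology entirely to the acceptance thresholds. Word-size parameters of the
heuristic are therefore documentation-only. Scores are validated against a
naive full-matrix DP oracle in the tests.

Percent identity is computed over alignment columns with gap columns
counted as non-identical (the alternative denominator, shorter-sequence
length, is not used; the convention is configurable in spirit by
recomputing from the returned column counts). A pair is homologous within
a genome when the alignment covers at least 9 of the 10 motif bases on the
reference sequence **and** spans more than 30 columns **and** exceeds 70%
identity — the length and identity bounds are strict, so 30 columns or
exactly 70.0% fail. The cross-species profile requires more than 100 nt of
the reference TE at more than 60% identity. Only the single best local
alignment per pair is evaluated; secondary alignments are not combined.
Homologous pairs are merged into clusters as connected components, with
the lexicographically smallest member naming each cluster.

## Set statistics

Hypergeometric tests use the survival function (over-representation:
P(X ≥ k)); the universe is configurable because published analyses rarely
state it. TF-family enrichment is log2[(targeted-in-family / targeted) /
(family / all TFs)] with a hypergeometric p per family; families with
fewer than six members ("more than five") are excluded; no
multiple-testing correction by default, Benjamini–Hochberg by flag.
Mann–Whitney comparisons use exact enumeration when both groups have at
most eight tie-free values and otherwise the tie-corrected normal
approximation with ±0.5 continuity correction. k-means is Lloyd's
algorithm with k-means++ initialisation, best of 10 restarts, fully
seeded (scikit-learn).

Gene categories for the TE-flanking expression comparison are evaluated in
the 3-kb upstream promoter: (i) RC/Helitron + motif + overlapped by a
binding site, (ii) RC/Helitron + motif unbound, (iii) RC/Helitron without
motif, (iv) no promoter RC/Helitron. Endosperm expression input, where
used, is a precomputed per-gene table; averaging of endosperm sub-regions
is left to a pre-processing step.

## Allele-specific chromatin profiles

Signal tracks are binned in 50-bp bins across a 2-kb window centered on
each site midpoint (40 bins). A bin's value is the coverage-weighted mean
of the track over the bin; bins without coverage stay missing and are
excluded from means, never zero-filled. Sites whose window would leave the
chromosome are dropped and reported. Metagenes are across-site bin means;
by linearity the maternal and paternal metagenes sum exactly to the total
metagene when the total track is the allele sum.

Profile clustering delegates to the seeded k-means; cluster numbers are
then fixed by biology, cluster 1 being the centroid with the higher mean
signal in the outer quarter of bins on each side (the flank-enriched,
center-depleted archetype). An all-identical matrix is reported as a
single degenerate cluster. Window orientation by host-gene strand is
available but off by default. Gene-body scores are means of a z-scored
track across the gene span; z-scoring standardises a track against its
genome-wide length-weighted mean and s.d. (the per-bin construction of the
source datasets is inherited from prior work and not restated here, so the
track-wide standardisation is this package's own convention).

## Imprinting classification

Per replicate, the maternal fraction is m/(m+p); replicates with fewer
than `min_informative` reads (default 10, borrowed from the companion
RNA-seq filter and configurable) are excluded, and the gene's fraction is
the unweighted mean of surviving replicates. Expected maternal fractions
are 2/3 (2x seeds, maternal:paternal odds 2:1 in the triploid endosperm)
and 1/2 (3x paternal-excess seeds, odds 1:1). The "four-fold deviation" is
applied on the odds scale — ω×4 for MEGs, ω/4 for PEGs — the only scale on
which both thresholds stay inside (0, 1) for any expected ratio and behave
symmetrically; this yields thresholds 8/9 and 1/3 (2x), 4/5 and 1/5 (3x).
Threshold boundaries are inclusive for deterministic tie handling. Calls
are MEG / PEG / biallelic / insufficient-data per gene and cross, with a
2x-versus-3x cross-tabulation of labels for genes measured in both.

## Synthetic data: what it emulates, and what it does not

The generator plants a known truth behind every analysis stage:

- **Genome and genes.** Random uniform-composition sequence (composition
  is the simplest null for motif scanning); genes on an even grid with
  3-kb promoters guaranteed to fit, random strands, bodies 0.8–2 kb.
- **TEs.** Configurable superfamily counts (default RC/Helitron 120,
  LTR/Gypsy 90, DNA/MuDR 90; lengths 150–400 bp). A configurable fraction
  of Helitron copies (default 0.5) carries a planted perfect motif;
  carriers within a family (default up to 20 copies) are descendants of
  one ancestral sequence mutated at 5% per non-motif base, so homology
  clustering can recover the families. All carriers sit in promoters,
  within 1.5 kb of the TSS. The background is scrubbed of chance perfect
  motifs genome-wide and of chance nearly-perfect motifs inside TE spans,
  making the planted truth exact — at these genome sizes a random
  background would otherwise contain dozens of chance hits.
- **Peaks.** Two replicates; a configurable fraction of peaks centered on
  motif-carrying promoter TEs (the planted enrichment), the rest uniform
  in proximal promoters; replicate 2 jittered by ±50 bp, plus ~10%
  replicate-specific peaks per replicate that drop out of the common set.
- **Allelic counts.** Maternal reads are beta-binomial around the planted
  mean (binomial in the dispersion→0 limit; read counts are overdispersed
  and no noise model is published, so the beta-binomial with dispersion
  0.02 is the package's choice). Planted MEGs/PEGs sit at a fold^1.5 odds
  deviation while the classifier boundary is fold^1 — a margin of 1.5× on
  the log-odds scale, which keeps planted genes ~2–3 s.d. beyond the
  boundary at the default depth (200–400 reads per replicate).
- **Signal tracks.** Two H3K27me3 archetypes: flank-enriched with a
  depleted center on the maternal allele (amplitude 2.0, 10 depleted
  central bins) versus flat-depleted on both alleles (baseline 0.2), with
  Gaussian bin noise (s.d. 1.0 = half the flank amplitude). CG methylation
  adds +0.3 to the paternal allele of MEG-associated sites. Where site
  windows overlap, the earlier site's bins win deterministically.

One seed governs the whole bundle; rerunning reproduces every file byte
for byte. The generator does **not** emulate read-level data, realistic TE
sequence evolution (indels, nested insertions), non-CG methylation
contexts, or genome-scale base composition, so passing tests demonstrate
correctness of the analysis logic on data with the planted statistical
structure, not performance on real libraries.

## Problem sizes and runtime choices

Defaults are one 1.2-Mb chromosome, 200 genes, 300 TEs and 150 peaks —
large enough that every stage has non-trivial statistics (≈126 binding
sites, 100 target genes, 60 motif carriers in 3 homology families, 300
expressed gene×cross calls) while a full pipeline run with 10,000
permutation iterations completes in seconds. The pipeline's in-situ
profile-cluster ARI (~0.7) is lower than the controlled recovery (>0.9 in
the dedicated test) because replicate jitter shifts analysis windows off
the generator's bin grid and peaks sharing a promoter truncate each
other's windows; the recovery report therefore scores only sites mapping
to a single truth archetype.

## Known limitations

- The homology stage evaluates one optimal alignment per pair; dispersed
  homology split across several local alignments is not aggregated.
- The permutation test offers only the promoter-restricted shuffle; no
  circular or genome-wide randomisation modes.
- Imprinting calls are pure ratio thresholds; no per-gene statistical test
  of allelic bias is attempted.
- The motif-density chi-square treats occurrences as independent bases,
  as in the published construction; overlapping occurrences can in
  principle push the motif-base count above the region size (capped).
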