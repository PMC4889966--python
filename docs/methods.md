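# Methods

This note records the models, parameter choices and numerical decisions
behind `smashcn`, and what the simulation-based tests do and do not
establish about behaviour on real sequencing data.

## Index and MAM search

The index text is the concatenation of every chromosome followed by every
reverse-complemented chromosome, each piece terminated by a sentinel.
Every sentinel — and every `N` base — receives its own unique integer
code, so no match can cross a piece boundary and `N` can never equal any
query symbol (query `N` is encoded as a code absent from the text). The
practical consequence is that MAMs are pure-ACGT by construction, which
mirrors the behaviour of conventional unique-mapping aligners on
ambiguous bases. Indexing both strands in one text means each read is
queried once in its given orientation; minus-strand hits surface through
the reverse-complement half and are mirrored back to forward coordinates.

The suffix array is built by numpy prefix doubling (O(n log² n), which on
drifting-GC random genomes terminates after the rank array becomes unique,
typically at prefix length ≈ log₄ n). The LCP table uses Kasai's
algorithm; per-read queries compute matching statistics (longest match and
suffix-array interval per query position) by per-character binary search,
compiled with numba. A substring is reported as a MAM when its count is
exactly 1, it is right-maximal (the matching statistic is by definition
the longest match) and left-maximal (the match starting one base earlier
does not cover it). "Almost-unique" means unique in the index while
possibly repeated in the query; repeats in the query are reported at each
occurrence.

## Countable maps

* **L:K rule** (default 20:4): a MAM of length M is kept iff M ≥ L and
  its trimmed substrings of length M−K are still unique. The operative
  reading demands **both** single-end trims unique; the disjunctive
  reading ("contains a unique substring of length M−K") is available as
  `lk_mode="either"`. The conjunctive default is the conservative choice
  and is what the tests validate.
* **Proximity filter**: maps of one read pair on the same chromosome
  within 10 kb are clustered transitively by anchor distance and reduced
  to the cluster's longest map (tie → leftmost). Keeping one
  representative rather than dropping the cluster retains depth evidence
  while preventing indel/SNP-split double counting.
* **Duplicates**: one pair retained per distinct multiset of
  (chromosome, position, strand, length); pairs with zero countable maps
  are dropped. The first-seen pair is kept, making the operation
  idempotent and input-order stable.
* **WGS arm**: read 1 clipped to 76 bp and kept iff the clipped sequence
  occurs exactly once in the index; duplicates removed by identical
  (chromosome, position, strand). This replaces an external aligner with
  exact-unique matching against the same index; on error-free simulated
  reads the two coincide, and it keeps the two arms of every comparison
  on the same footing. Read 2 is not used.

Map anchors are the leftmost matched reference base — deterministic and
strand-independent, so bin assignment does not depend on orientation.

## Bins

Bin boundaries equalize expected unique-map content: the per-position
mappability mask marks positions whose 50-mer (no `N`) occurs exactly
once in genome ⊕ reverse complement, and boundaries are placed after
successive quantiles of mappable positions. When the genome-wide quotient
is compatible with every chromosome (always for a single chromosome, and
generally when bins per chromosome exceed √(mappable positions)), every
bin holds ⌊T/n⌋ or ⌈T/n⌉ mappable positions exactly; otherwise bins are
allocated to chromosomes by largest remainder and the ±1 split applies
within each chromosome. Bins never span chromosomes; a bin's bp width
grows over mappability deserts while its content does not.

Bad bins: per sample, counts (+1) are mean-normalized; after bin-wise
summation across samples, a bin is masked when its upward deviation from
the chromosome median exceeds 1.4826·MAD·z with z the upper normal
quantile at 0.05/n_bins (Bonferroni). Only upward deviations are masked —
downward outliers are potential deletions, not artifacts. The 1.4826
factor is the standard MAD→σ consistency constant for normal data. The
summation uses mean-normalized, pre-GC counts.

## Normalization

* +1 pseudocount on every bin (sample and reference alike), then scaling
  so the mean over non-bad autosome bins is exactly 1.
* GC correction divides by a LOESS (locally linear, 2 robustness
  iterations, span 0.3) fit of ratio vs bin GC on autosome bins,
  evaluated everywhere by interpolation over GC, then re-centers the
  autosome mean at 1. Span 0.3 is conventional for 10²–10⁴ bins and is
  exposed as configuration. The fit is performed on mean-normalized
  ratios rather than raw counts (equivalent up to the global constant).
* Reference normalization divides by an independent sample's track
  processed identically; bins with missing/zero reference become missing,
  and the autosome mean is reset to 1. A depth-matching mode subsamples
  the reference's maps to the sample's total first. Missing markers
  propagate through all later stages and are excluded from statistics and
  segmentation.

## Segmentation and quantal fit

CBS operates on linear ratios per chromosome (non-missing bins only). The
split statistic is the unweighted two-sample t numerator
|mean_in − mean_out|/√(1/k + 1/(n−k)) maximized over circular arcs; its
significance is assessed by permutation (default 10,000, seeded), with
early termination as soon as the exceedance count makes p > alpha
certain. Arcs are constrained so every resulting piece is empty or at
least `min_seg_len` (3) bins — the constraint lives in the search, so
sub-minimum segments can never be emitted. Because raw recursive
splitting over-segments, adjacent segments are re-tested after recursion
and merged (least-significant pair first) while their difference fails
the alpha level. Chromosomes are processed independently with seeds
derived per chromosome, so concatenation order cannot change results.

The quantal fit minimizes Σ n_bins·(s·mean + o − round(s·mean + o))² over
a 0.01-step grid with s ∈ [1, 4], o ∈ [−0.4, 0.4], refined by
Nelder–Mead. The objective is scale-periodic (a diploid profile fits at
s and 2s equally well), so ties resolve to the smallest s in bounds —
the near-diploid prior. A profile with a single level cannot identify s;
it is assigned the diploid interpretation and flagged low-confidence.

## QC statistics

MAD is unscaled median absolute deviation. Autocorrelation is lag-1
Pearson within chromosomes, pooled by lag-pair-count weights (a
between-chromosome level shift therefore contributes nothing). S/N for a
male sample is (median_auto − median_X)/√(MAD_auto² + MAD_X²) on
unsegmented ratios; a noiseless track yields infinity, reported as a
flagged sentinel rather than a number. Note that at an autosome depth of
λ maps/bin the X bins of a male receive ≈ λ/2 maps, so the Poisson
prediction is 0.5/√((0.6745√λ/λ)² + (0.6745√(λ/2)/λ)²) — the X term uses
the half depth.

## Simulator

What it emulates, with defaults chosen once as the study conditions:

* fragment lengths: truncated normal, mean 45 bp, sd 10, range 20–150 —
  a parametric stand-in for the observed short-fragment size profile
  ("average length 40–50 bp");
* chimera assembly: fragments ligated in random order and orientation
  (blunt-end ligation has no directionality), accepted when total length
  falls in the 300–700 bp size-selection window; junction artifacts are
  therefore realistic exercises of the L:K filter;
* reads: 2×125 by default (2×101/2×150 configurable) from the chimera
  ends, read 2 reverse-complemented; substitution errors at 0.001/base
  (typical short-read error rate); constant qualities (the mapper is
  quality-blind);
* PCR duplicates: each emitted pair is, with probability 0.05, a re-read
  of a random existing molecule with independent sequencing errors;
* copy number: per-position sampling weights proportional to integer copy
  number (autosomes 2, male X/Y 1), overridden by non-overlapping CNV
  intervals; weight 0 regions emit nothing;
* GC bias: fragment acceptance ∝ 1 + β·(GC − 0.5), β = 0.5;
* systematic noise: a lognormal (σ = 0.1) per-10-kb multiplicative field
  generated from a *batch* seed shared across samples, which is exactly
  the structure reference normalization cancels;
* genomes: i.i.d. bases under a smoothly drifting GC probability (AR(1)
  block process, amplitude 0.08), optional planted exact duplications
  for mappability tests;
* the WGS arm: contiguous 300–700 bp inserts under the same weight,
  error and duplicate model.

What it does **not** model: restriction-site sequence bias, donor
variants (SNPs/indels) beyond substitution errors, instrument-specific
error profiles, chimeras formed preferentially between nearby loci, and
real-genome repeat structure (segmental duplications beyond the planted
exact copies, satellite arrays). Passing tests therefore demonstrate the
pipeline's correctness and its statistical behaviour under the assumed
noise structure, not performance on human data; in particular real
repeats would lower mappable fractions and maps per pair.

## Problem sizes

Tests run on 0.1–2 Mb genomes with hundreds of bins and thousands of read
pairs; the acceptance script uses 2-Mb (binning), 5-Mb (10,000 pairs,
maps per pair) and 10-Mb (two-arm concordance, 1,000 bins at ≥50
maps/bin) genomes. These sizes were chosen so that every quantity is
stable (binomial/Poisson standard errors well inside the asserted
margins) while a full run stays in minutes on one CPU. The suffix-array
prefix-doubling build is the dominant cost and scales n log² n; 10 Mb
(20 Mb of indexed text) builds in ~1.5 minutes.

## Known limitations

* The suffix-array builder targets desk-scale genomes; a human-scale
  index would want an SA-IS construction and memory-mapped arrays.
* CBS permutations use the full max-statistic null; very long
  chromosomes (≫10⁴ bins) would benefit from the hybrid tail
  approximation used by mature CBS implementations.
* The quantal fit assumes a near-diploid baseline (s ≤ 4); high-ploidy
  tumours would need wider bounds and an explicit ploidy prior.
* Mappability is exact-unique only; mismatch-tolerant mappers admit
  slightly more positions.
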