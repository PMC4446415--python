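# Methods

## The model

Short reads of length L sampled from a repeated sequence cannot be assigned
uniquely to their locus of origin: any locus whose sequence differs from the
origin by a handful of substitutions within the read window is an equally
valid placement. The package models this ambiguity explicitly with a
*thesaurus table*: a sorted list of entries, each pairing an **origin**
interval with an **alternate** interval of equal length, an orientation
(`+`/`-`), and the recorded substitution differences between the two
sequences. The table is a property of the reference genome alone — it is
built once and then consulted for any sample.

Annotation is a decoration step on an existing call set: calls are never
added, removed or reordered. For each called SNV inside a thesaurus region,
the variant-carrying reads are tested against each overlapping entry, and a
link to the projected alternate site is emitted when enough of them are
consistent with the entry. Links between called variants induce a graph
whose connected components are *clusters*; link targets that coincide with
no call attach to their cluster as peripheral sites.

Assumptions: substitutions only (entries carry no indel information — reads
whose alignments contain indels or splice junctions instead mark the variant
`TS_INDEL`); a single haploid/clonal sample per VCF; 1-based inclusive
coordinates throughout, matching VCF/SAM.

## Building the table

Construction tiles the reference with error-free reads (length 100, step 10)
and enumerates every ungapped placement of each read with a terminal-seed
all-mapper:

- candidate placements are exact matches of the read's **first or last
  5 bases** on either strand (found with a sorted k-mer index);
- a candidate is kept if the full read aligns with **≤ 4 mismatches** and
  **no mismatch in the first or last 5 bases** (the seed region must be
  clean by construction).

Because both terminal 5-mers are mismatch-free in any accepted placement,
seeded search finds exactly the placements an exhaustive Hamming scan
admits; the test suite asserts this equivalence on randomized genomes. A
read whose *own* terminal bases overlap a divergent position can still miss
a placement, but neighbouring reads tiled 10 bp away recover the same
region, and the merge step below stitches their entries together.

Alternate placements with **≤ 3 mismatches** become entries, with mismatch
positions recorded in origin coordinates and alternate-side bases
strand-normalized (reverse-complemented for `-` entries). Each region pair
is written once, canonically ordered; the table's symmetric query returns
flipped entries for lookups that land on the alternate side. Entries sharing
(origin chromosome, alt chromosome, strand, diagonal offset) whose origin
intervals overlap or abut are merged, mismatch lists unioned — merged
entries may therefore carry more than three recorded mismatches over a long
region. Finally each merged region is extended 10 bp (= the tiling step, so
the extension exactly covers the inter-read sampling gap) both directions,
clipped so origin and alternate intervals remain equal length within their
chromosomes, and the table is sorted by origin coordinate. Only exact
diagonals merge; near-diagonal jitter would indicate an indel, which the
table deliberately does not represent.

## Annotation rules

For a called SNV with variant-carrying read observations and a candidate
entry covering its position, a read is *consistent* with the entry when each
of its mismatches against the reference is explainable as

1. an entry-recorded difference (read base equals the recorded alternate
   base at that position),
2. a called variant at the mismatch position (this includes the variant
   being annotated), or
3. a called variant whose position and strand-projected allele match the
   mismatch after projection to the alternate side,

with at most `max_extra_mm = 2` residual mismatches tolerated as sequencing
errors. A link is declared when at least `min_reads = 2` variant-carrying
reads are consistent **and** they are at least `min_fraction = 0.5` of all
variant-carrying reads. Variants linked to more than `max_links = 100` sites
are marked `TS_MANY` with links suppressed; variants supported by any read
with an indel/splice gap are marked `TS_INDEL`; variants supported by a read
with more than `error_cap = 4` non-variant mismatches — more than the
mapper itself tolerates, so no entry can explain it — are marked
`TS_ERRORS`. Links are stored in the `TS_ALT` INFO key (annotation) while
marks go to FILTER (actionable for downstream exclusion). The published
description states that these thresholds exist but not their values; the
defaults here require corroboration beyond a single read while keeping
recall, and all are exposed as flags.

Clustering joins calls whose link targets coincide positionally
(tolerance `merge_tol = 0`; the build-time extension already absorbs
coordinate jitter) using union-find; an independent graph-library oracle
checks the components in the tests.

## Pooled B-allele frequency

Per-site BAF (variant reads / depth) underestimates the allele frequency of
a haploid variant whose evidence is scattered: each similar locus holds only
a fraction of the variant reads but a full complement of reference reads
from its own copy. Pooling therefore **averages over loci**: the pooled BAF
of a cluster is the total number of variant-supporting reads across all
member and peripheral sites divided by the *mean* depth per site. For a
variant scattered over k similar copies this recovers ≈ 1.0 (all variant
reads are collected; the denominator stays at one locus's worth of
coverage), whereas the plain ratio of sums — also reported, as
`pooled_fraction` — stays near 1/k. Zero-depth sites are skipped. A read
overlapping two cluster sites would be counted at both; with sites typically
on distinct repeat copies separated by more than a read length this does not
arise in practice.

## Evaluation conventions

- **TN convention.** The number of true negatives is fixed to the genome
  length (the same convention used at full scale with TN = 3×10⁹), so
  FPR = FP/(FP + L). For the worked example this gives 3/1003 ≈ 0.003.
- **Allele matching.** TP and TTP require the called (strand-projected)
  alternate allele to match the truth allele, not just the position;
  `position_only=True` relaxes this.
- **TTP counting.** Every called site that is not itself a true locus but
  links to one counts as a TTP — including a wrong-locus call whose true
  counterpart was never called (that call simultaneously rescues the FN).
  In the worked example all three local FPs are linked to true sites, so
  TP=2, TTP=3, FP=0, FN=0, FPR=0, TTPR=1.
- **Rates** are computed in exact rational arithmetic and returned as
  floats; a zero denominator yields a missing value (`None`), not an
  exception.

## Error-rate estimation

The apparent sequencing error rate of a region class is the number of
mismatched aligned bases over total aligned bases at positions in the class
that are not labelled as variants. The *covered* class is the union of all
entry intervals (origin and alternate sides). Three exclusion policies:
none; excluding the alternate sites linked to called variants; and a control
excluding an equal number of uniformly drawn in-class positions, repeated
5 times with mean and standard deviation reported. Scattered variant reads
deposit their variant base at alternate loci, so the covered-region rate is
inflated relative to uncovered sequence, drops when linked alternate sites
are excluded, and is essentially unchanged by the random control. With
error-free reads the repeats of the random control can be numerically
identical (sd ≈ 0); comparisons therefore use
`max(repeat sd, binomial standard error of the rate)` as the measurement
uncertainty floor.

## The simulator

The synthetic genome is i.i.d. uniform A/C/G/T background with pasted repeat
families: each family is a random consensus whose copies are substituted
independently at half the nominal divergence, giving the stated pairwise
divergence between copies. Copies are placed at random non-overlapping
positions with a minimum 150 bp gap. Planted SNVs use per-base binomial
sampling at `rate/1000` (a rate, not a fixed count). Shotgun reads sample
the mutated genome either at regular intervals (stride = read length /
coverage, so interior depth is exact) or uniformly at random, on random
strands, with substitution-only errors at a constant rate (default 0 — on
error-free data any false or missed call is attributable to mappability
alone); paired-end mode uses a fixed 300 bp insert. Every generator is a
pure function of its seed.

What the simulator does **not** model: indels and structural variation,
quality-score variation, GC/coverage bias, diploid genotypes, divergence
other than substitutions. Passing benchmarks therefore demonstrate the
mappability-driven behaviour of the method, not robustness to those
real-data artefacts.

Reads are placed by the package's own all-mapper, choosing uniformly among
minimal-mismatch placements — the random multi-mapping behaviour of
production aligners — with mapping quality 60 (unique), 20 (unique best
among several) or 0 (tied best).

## Benchmark conditions

The standard benchmark uses a 100 kb genome with 3 repeat families × 5
copies at 1% pairwise divergence, SNVs at 1/kb, error-free 10× single-end
reads, and calling at mapping-quality threshold 0. The repeat unit is
5000 bp — segmental-duplication scale — so that low-mappability sequence is
75% of the genome, the regime the method targets. The benchmark caller runs
in a lenient regime (`min_reads = 2`, `min_fraction = 0.3`): evidence
scattered over k similar copies leaves only ~1/k of the variant reads at any
one locus, so the wrong-locus candidates the thesaurus links act on only
surface below the 0.5 fraction expected of unscattered haploid evidence.
This mirrors benchmarking with the most permissive of the production
callers, which emits the largest candidate set at lenient mapping-quality
thresholds. The 100 kb scale keeps a full simulate–build–annotate–classify
cycle under ~15 s on one core while leaving ≈ 100 planted variants and
dozens of ambiguous sites per run.

## Numerical and degenerate-input choices

- Pileup calling resolves ties between alternate bases alphabetically;
  calls are emitted in coordinate order; reference-N columns are skipped and
  N read bases never count as support.
- Reads containing non-ACGT bases are not seeded or extended (counted and
  skipped); genome k-mers containing N never match an ACGT query (base-5
  encoding keeps the codes disjoint).
- The thesaurus writer rejects unsorted input; the reader reports malformed
  lines by line number; gzip is selected by the `.gz` suffix.
- Unknown chromosomes in a query return empty results; a VCF chromosome
  missing from the reference is a hard error naming the chromosome.
- Interval extension at chromosome ends is clipped symmetrically so origin
  and alternate intervals keep equal lengths.

## Limitations

- Table construction is quadratic-ish in repeat content and held in memory;
  the implementation targets method-scale genomes (≤ a few Mb), not a full
  human build.
- Only substitution divergence is represented; copies differing by indels
  are invisible to the table (affected variants are marked instead).
- The naive pileup caller is a stand-in for production callers; all
  evaluation functions also accept externally produced VCFs.
- BAM requires an index for region fetch only through the SAM/BAM reader;
  plain coordinate-sorted SAM is the tested path. CRAM and tabix indexing
  are out of scope (the sorted table uses binary-search/interval queries).
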