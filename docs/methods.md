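# Methods

This note documents the statistical model and procedures implemented in
`avinc`, the parameter defaults and their rationale, and the scope of the
synthetic-data generator.

## Coordinates and formats

Internally every interval is 0-based, half-open, with an explicit strand.
Conversions happen only at the I/O boundary:

- **cmsearch `--tblout`**: 18 whitespace-separated columns, 1-based inclusive
  coordinates; a hit with `seq from > seq to` is on the minus strand. The
  parser checks that the coordinate order agrees with the printed strand
  column and reports the offending line number otherwise. The family
  identifier is the query accession when present, else the query name.
- **tRNAscan-SE** tabular output: three header lines ending in a dashed
  separator; `Begin > End` means minus strand; an isotype of `Pseudo` marks a
  pseudogene. tRNAscan hits carry a pseudo E-value of 0.0 (the tool reports
  none), which deliberately ranks them above Rfam tRNA hits in clan
  competition — the specialised finder wins where both detect the same locus.
- **GFF3 / BED6** output for annotations, BED6 input for reads. BED scores
  are capped at 1000 per the format; GFF3 attributes carry family, clan,
  class, E-value, bit score and number of merged hits.

Writers are byte-stable: writing and re-reading reproduces the objects, and
re-writing reproduces the text. Scores and E-values are rendered with enough
precision that round trips are exact.

## Hit consolidation

1. **Filtering.** A hit survives iff `E-value ≤ evalue_max` (default
   `5e-4`) and, when GA filtering is enabled, `bit score ≥` the family's GA
   threshold. Both comparisons are inclusive.
2. **Clan competition.** Hits are grouped by scaffold and clan (clanless
   families form singleton groups, so same-family overlaps still compete).
   Within a group, hits are ranked by (E-value ascending, bit score
   descending, family id, start, end) and accepted greedily; a candidate is
   dropped if it overlaps an already accepted hit by ≥ 1 bp. Competition is
   strand-agnostic: clan members can hit either strand of one locus, and
   double annotation must be prevented. The greedy-by-rank rule matches
   Rfam's clan-competition semantics and is verified in the tests against an
   independent brute-force implementation on thousands of random instances.
3. **Overlap collapsing.** Surviving same-family, same-strand, same-scaffold
   hits whose intervals overlap are merged into one annotation spanning their
   union, keeping the minimum E-value, maximum bit score and the merge count.
   Collapsing is strand-aware (a merged locus must have a coherent strand),
   and pseudogene hits collapse separately, yielding a "… pseudogene" class.

## Conservation analysis

The copy-number matrix counts annotations per (family, genome). The
conservation filter retains a family iff it is present (count ≥ 1) in at
least `ceil(min_genome_fraction × n_genomes)` genomes; the default fraction
is 0.10, so with 48 genomes a family needs ≥ 5 genomes. The ceiling is
computed as `ceil(frac × n − 1e-9)` because the naive product suffers float
artefacts (`0.1 × 30 = 3.0000000000000004` would otherwise require 4
genomes).

A family is *flagged missing* when it is absent from more than
`missing_absent_fraction` (default 0.5) of the genomes. Microchromosome
enrichment asks whether flagged families sit preferentially on
microchromosomes: each family is mapped to the scaffold of its locus in the
reference genome, scaffolds are labelled micro/macro from a user-supplied
table (unlabelled scaffolds are excluded), and the 2×2 table
{missing, not missing} × {micro, macro} is tested with a one-sided (greater)
Fisher's exact test. The p-value comes from `scipy.stats.fisher_exact`; the
odds ratio is the sample estimate `ad/bc` (infinite when `bc = 0`), and
p-values below 1e-300 are rendered as `"<1e-300"`.

## Expression validation

Reads overlap an annotation when they share ≥ 1 bp; counting is strand-aware
by default, and a read overlapping several annotations counts for each (no
deduplication). There is no length normalisation — instead the null is
length-matched:

1. **Null sampling.** Region lengths are drawn with replacement from the
   annotation length distribution; positions are uniform over scaffolds
   weighted by length; candidates overlapping any annotation are rejected and
   re-drawn (an error reports the un-annotated fraction if placement fails
   repeatedly). Sampling is deterministic given a seed.
2. **Threshold selection.** The expression-call threshold is the smallest
   count `c ≥ 1` such that the fraction of null regions with count ≥ `c` is
   ≤ the target false-positive rate (default 0.10). The exceedance fraction
   is non-increasing in `c` and reaches zero at `max(null) + 1`, so the
   minimum always exists.
3. **Calling and summary.** An annotation is expressed iff its count ≥ the
   threshold (inclusive). The per-class summary reports annotated and
   expressed counts with percentages rounded half-up to one decimal (decimal
   arithmetic, matching published-table formatting). Overall enrichment is
   the expressed fraction of annotations divided by the null exceedance
   fraction, with a one-sided Fisher test on
   {expressed, not} × {annotation, null region}.

Because the threshold is chosen on one finite null draw, its false-positive
rate on fresh data is a random variable concentrated near (at or below) the
target; the acceptance script measures exactly this on an independent,
separately seeded draw.

## Synteny of lncRNA RNA-domains

A lncRNA is modelled as an ordered list of domain families. Annotations of
those families are grouped per (genome, scaffold) and split into clusters
whose genomic extent does not exceed `max_span` (default 1 Mb) — distant hits
on one large scaffold are separate loci. A cluster is *consistent* when one
occurrence of each observed domain can be chosen so that the chosen
occurrences, in genomic order, form a subsequence of the reference order
(orientation "forward") or its reversal ("reverse"). Since reference ids are
unique, greedily matching the leftmost usable occurrence per reference id is
optimal; the tests verify this against exhaustive enumeration over duplicate
choices. Clusters with fewer than two domains are vacuous (consistency
`n/a`): order is undefined for a single point.

## Synthetic-data generator

The simulator produces genuine text fixtures (tblout, tRNAscan, BED, TSV)
with known ground truth, deterministically for a given seed. Design choices
that matter for its use as a test oracle:

- **Exact planting.** A family with conservation fraction *cf* is planted in
  exactly `round(cf × n_genomes)` genomes (the reference genome always
  included), not in a Bernoulli sample — conservation-filter tests can then
  assert exact retention/removal. Likewise, exactly
  `round(expressed_fraction × n)` reference loci are expressed, removing
  binomial noise from the planted expressed fraction.
- **Read model.** Expressed loci receive `Poisson(lambda_hi)` reads (default
  50), silent loci `Poisson(lambda_lo)` (default 0.5), each read a fixed
  25 bp placed to overlap its locus. Background noise reads are scattered
  over un-annotated space at a per-base rate of
  `2·lambda_lo / (mean_length + read_length − 1)` with uniform strand, so
  that strand-aware counts over random un-annotated regions are approximately
  `Poisson(lambda_lo)` — the null the threshold calibration assumes.
- **Decoys.** Each genome receives filter-failing decoys (half with E-values
  above the cutoff, half below the GA score) and, with some probability per
  true locus, an overlapping clan-mate hit with a worse E-value that must be
  eliminated by clan competition. On default settings consolidation recovers
  the planted loci exactly.
- **Chromosome classes.** Reference scaffolds are labelled micro/macro;
  micro scaffolds are drawn an order of magnitude shorter (as in avian
  karyotypes), and low-conservation ("missing") families are placed on micro
  scaffolds with configurable probability, planting a detectable enrichment.
- **Scope.** The generator emits hit files directly; it does not simulate
  sequences, alignment scores beyond plausible ranges, assembly gaps, or
  mapping ambiguity. E-values and scores are pre-rounded so rendered files
  parse back to identical objects.

## Numerical and testing notes

- Fisher p-values are validated against an exact-rational hypergeometric
  enumeration oracle (exhaustively for table totals ≤ 14, randomly to 40),
  including the worked value 17/70 for table (3, 1; 1, 3).
- Clan competition, read counting and the synteny subsequence check are each
  validated against independent brute-force oracles on randomized instances.
- `IntervalTree` deduplicates identical intervals, so read trees store a
  unique per-read payload; duplicate reads (same coordinates and strand) are
  counted correctly.
- The pipeline manifest (`manifest.json`) records the package version, every
  threshold, the seed and per-stage counts, and contains no timestamps, so
  identical inputs produce byte-identical report bundles.
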