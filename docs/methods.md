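# Methods

## Scope and model

The package analyses two-pool (male vs female) pooled resequencing of a
population segregating a ZW sex determiner, together with the downstream
characterisation of the sex-linked region: inversion calling from pairwise
whole-genome alignment blocks, TE window statistics, microsatellite diversity
and gonadal expression contrasts. It does not align reads, call variants,
assemble genomes or annotate repeats; it consumes the tabular products of
those steps (sync count tables, alignment coordinates, BED annotations, FPKM
tables, genotype tables).

## Coordinates and formats

All in-memory coordinates are 0-based half-open; conversions happen at I/O
boundaries only. Sync positions are 1-based (Popoolation2 convention) and a
site at 1-based position p belongs to the tiling window containing p − 1,
matching bedtools semantics. `N` and `del` sync fields are parsed but excluded
from depth and frequencies: the scan concerns nucleotide SNPs. show-coords
rows are 1-based inclusive with reverse alignments encoded by descending query
coordinates; both are normalised on read, and normalisation is idempotent.
The parser never drops data silently — low-depth sites are counted and
reported, malformed lines raise errors naming the line.

## Pooled sampling model

The generator draws reads in two stages per site and pool: the 2N gene copies
of the pool are sampled binomially from the population frequency of that sex,
then read depth is Poisson(pool_size × per-individual coverage) and allele
reads are binomial in the realised pool frequency. The two-stage form matters:
with pools of 20 fish the pool frequency of a W allele (population 0.5 in
females) has standard deviation ≈ 0.08 before any sequencing, which is
exactly why the classifier accepts 0.3–0.7 rather than demanding 0.5. A
corollary worth knowing: between-pool differentiation does not vanish with
sequencing depth alone. Under the null of no sex linkage the mean G_ST
between the two pools levels off at about 1/(2·2N) ≈ 0.013 for N = 20 —
approaching zero requires large pools *and* depth, and the test suite checks
both regimes. Individuals are assumed to contribute equally to the pool
(equimolar pooling); unequal contributions would inflate the finite-pool
variance beyond what the defaults emulate.

One global seed drives the generator; each operation (population, counts,
TE placement, alignment blocks) derives an independent substream from it, so
outputs are reproducible individually and jointly.

## Generator defaults

The defaults encode the sampling design the package targets: a 31 Mb
chromosome; a sex region [14.5, 23.1) Mb; 860 W-diagnostic SNPs (10 per
100 kb window — the scan needs only that elevated densities dwarf the
background, and this density leaves the region call robust to per-window
detection noise); 5000 sex-independent background SNPs with frequencies
uniform on [0.05, 0.95] (enough to measure false-call rates without paying
for a realistic genome-wide SNP count); pools of 20 at 1× each; a 6.89 Mb
inversion at [14.5, 21.39) Mb emitted as reverse alignment blocks with a
1.3 Mb query expansion; TE base rate 0.27 with three 400 kb peaks at rate
0.5, which averages ≈ 0.31 inside the inversion. TE placement is Bernoulli
per 100 bp segment (merged afterwards), so the expected per-bp TE fraction
equals the local rate. What the generator does *not* emulate: linkage
disequilibrium and haplotype structure, sequencing error, mapping artefacts,
reference bias, and non-uniform coverage. Recovery tests therefore
demonstrate correctness of the statistics and calling logic under the stated
sampling model, not robustness to real-data artefacts.

## Classifier

ZW: some allele has female-pool frequency strictly inside (0.3, 0.7) while
the male pool's major *other* allele exceeds 0.9; XY is the exact mirror. All
cutoffs are strict inequalities. Fixation is assessed on the complement of
the diagnostic allele so that low-level sequencing error at a truly fixed
site cannot veto a call. With fixation cutoff > upper polymorphism cutoff the
two patterns are mutually exclusive; the code still guards the impossible
double match (reachable only with looser user-supplied cutoffs) and returns
`none` with a warning. When several alleles qualify, the one with the highest
frequency in the polymorphic sex wins (alphabetical tie-break) — a rule
chosen to keep the male/female pool swap an exact ZW↔XY bijection. The
default minimum depth is 4 per pool: below that a 0.9 fixation cutoff cannot
be meaningfully exceeded or refuted.

## Region calling

Window densities of ZW-patterned SNPs are scanned for maximal runs of
windows ≥ 5 calls/100 kb, tolerating up to 8 consecutive below-threshold
windows inside a run — sized to bridge the several-hundred-kb TE-dense
stretches that suppress SNP calling inside inverted sex regions — and
discarding runs with fewer than 10 elevated windows. The reported interval
runs from the first to the last elevated window, so boundary resolution is
one window. The density threshold is a tunable (no principled universal
value exists); the default separates the simulated in-region density (~8-10
detected ZW SNPs per window) from the background false-call density (< 0.5)
by an order of magnitude on either side.

## Inversion calling

Minus-strand blocks shorter than 10 kb are discarded (short reverse
alignments are typically repeat artefacts), the rest are chained along the
target while consecutive gaps are ≤ 100 kb, and each chain becomes one call.
Gaps are measured against the running maximum target end so nested blocks
cannot split a chain. The model is a single simple inversion per chain;
nested or overlapping inversions, translocations and duplications are out of
scope. Breakpoint comparisons take an explicit tolerance because block edges
on real assemblies carry alignment uncertainty of the order of the chaining
gap. The length delta (query span − target span) measures expansion of the
inverted haplotype relative to the reference; it is exact on simulated
blocks because the generator books the inserted length explicitly.

## TE comparison

Window fractions are computed on merged annotation intervals, so the
conservation identity Σ fraction × window length = merged TE bp holds
exactly. The inside/outside comparison uses Welch's unequal-variance t-test,
one-tailed for enrichment inside the inversion; Student's equal-variance
variant is available by flag. Windows are assigned by midpoint. Truncated
final windows shorter than half the window size keep their fraction in the
table but are excluded from the test groups, since grossly unequal window
lengths violate the per-window variance framing. A label-permutation check
in the test suite confirms the parametric p agrees with a 10,000-shuffle
permutation p to within 0.02 at the fixture sizes used.

## Diversity and expression statistics

N_e = 1/Σ p_i² is computed on raw sample frequencies per group × locus with
no small-sample correction. Private alleles use strict absence (min_freq = 0)
by default: an allele is private when observed in exactly one group at a
locus. Fold changes are log₂(female/male) — ovary-biased genes positive —
with ε = 0 by default so published FPKM tables reproduce exactly; single
zeros yield signed infinities (direction preserved), double zeros are
missing. The DE filter (|lfc| ≥ 2 and max FPKM ≥ 1) is an explicit,
configurable stand-in for the fitted DE machinery that produced such tables
upstream; it is a selection rule, not a significance test. Allele-specific
expression uses the Wilson score interval, which behaves well at the extreme
proportions typical of W-dominated expression.

## Numerical choices

G_ST uses the unweighted mean of the two pool frequencies (pools are
equal-sized by design) and returns missing, never 0, when H_T = 0. The exact
small-table enumeration in the tests uses rational arithmetic, eliminating
tolerance questions in the oracle itself. Problem sizes in the test suite
(31 Mb single chromosome, 20 recovery seeds, 10⁴ permutation shuffles,
depth-2000 calibration runs) were chosen so the complete suite exercises
every recovery property in well under a minute per test while keeping
binomial/Poisson noise far from the asserted margins.

## Known limitations

Single-chromosome simulation only; no LD, no sequencing error model, no
coverage waves. The scan assumes exactly two pools of equal design. Inversion
calls assume one query chromosome per target chain and do not refine
breakpoints from sequence. The expression module reproduces summary
arithmetic on FPKM tables; it does not estimate expression or test counts.
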