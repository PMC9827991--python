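# Methods

## Problem and approach

Plant telomeres are tandem arrays of the heptamer TTTAGGG; in some
lineages (most strikingly the cycad genus *Cycas*) arrays also contain
high proportions of variant heptamers such as TTCAGGG, TTTAAGG and the
double mutant TTCAAGG, and telomere-like repeats occur in megabase-sized
interstitial/pericentromeric blocks. Because such arrays collapse in
assemblies, the abundance and heterogeneity of the repeat fraction is
best measured directly from unassembled low-coverage ("genome-skimming")
reads. `telospect` implements that read-level estimator, the downstream
heterogeneity measurements, an in-silico analogue of the restriction
digests used to confirm variant interspersion, and the cross-species
association statistics, with a seeded simulator that provides exact
construction-time truth for all of it.

## Read classification and abundance

The reference is periodic: `copies` tandem repeats of the 7-bp motif,
default (TTTAGGG)₁₄ = 98 nt. A read aligned to this reference gap-free
can only match in one of 7 frames per orientation, so the classifier
scans both orientations and all 7 frames. A *unit match* is an in-frame
7-bp window with at most `max_mismatches_per_unit` (default 1) mismatches
to the motif; ambiguity codes count as mismatches. The longest run of
consecutive unit matches is found per orientation x frame, and the read is
accepted iff

1. `run_units >= min_consecutive_units` (default 8),
2. `7 * run_units / read_length >= min_telomeric_fraction` (default 0.60),
3. identity over the run `>= min_identity` (default 0.80).

Ties between candidate alignments are broken by higher identity, then
G-strand, then lower frame. With the default per-unit mismatch cap of 1
the identity over a run is at least 6/7 ≈ 0.857, so rule 3 is not binding
at defaults; the cap of 1 is deliberate so that single-substitution
variant units (TTCAGGG, TTTAAGG, ...) extend runs and variant-rich arrays
are still captured, while the run and fraction rules keep random
background out. The scan is gap-free because telomeric arrays are
indel-poor at the unit level and the acceptance rules are phrased in whole
units; the test suite holds the streaming implementation to exact
agreement with a brute-force oracle that enumerates every
orientation x frame x run alignment.

The quality filter passes a read iff the fraction of bases with
Phred > 30 is at least 0.90; no trimming is performed. Genome proportion
is `GP = 100 x mapped / passing` reads and absolute abundance is
`(GP/100) x genome size (Mb/1C)`. Read-count GP approximates
base-proportion GP under uniform read length. These rules deliberately
target long, relatively homogeneous arrays; loci with runs shorter than
~8 units are invisible to the estimator, and a read-level method cannot
localize arrays (terminal vs interstitial).

## Variant spectrum and SNV heterogeneity

Accepted reads are oriented to the G-rich strand (only one strand is
profiled) and cut into non-overlapping in-frame 7-bp windows starting at
the classifier's frame; partial leading/trailing windows are discarded.
Non-overlapping windows make the spectrum frequencies sum to exactly
100%. Each window is assigned to the motif with fewest mismatches in a
list of the canonical motif, all 21 single-substitution variants
(7 positions x 3 alternative bases, enumerated by position then base), and
configurable extras (default TTCAAGG) — 23 motifs in total; ties go to
the canonical, then list order, and windows more than 2 mismatches from
every listed motif are counted unassigned. Frequencies are percentages of
assigned windows; motifs at >= 10% are flagged abundant (all frequencies
are reported, so filtering before or after rendering is the caller's
choice).

For SNV calling the windows are tiled back onto the linear 98-nt
reference, wrapping circularly, to form a per-position pileup. Only the
modulo-7 congruence class of a position is biologically meaningful, so
each read's anchor unit rotates deterministically with read index; this
keeps the pileup even for any read length (the reference is reported in
linear coordinates because that is how such references are conventionally
displayed, with a modulo-7 collapsed summary alongside). A call is made
for every (position, alternative base) with coverage > 400, variant
count > 40 and frequency > 20% — all strict inequalities — and the total
number of calls is the heterogeneity metric. Under this geometry a single
variant at array proportion p in (0.25, 0.75) with deep coverage produces
calls at all 14 congruent positions of the 98-nt reference, each at
frequency ≈ p; that closed-form expectation anchors the tests. The
coefficient of variation of per-position coverage is reported as a
uniformity QC statistic.

## In-silico digestion

Tru1I (TTAA), TaqI (TCGA) and HaeIII (GGCC) have no recognition site in
pure (TTTAGGG)ₙ for any n, so a homogeneous array yields a single
high-molecular-weight fragment — the in-silico analogue of probe signal
staying at the top of the gel. Every TTTAAGG unit contributes exactly one
TTAA, so for an iid mixture with per-unit variant probability p the
inter-site spacing is geometric with mean 7/p bp; a 10% TTTAAGG array
digests to ~70-bp mean fragments. Arrays are digested as linear molecules
(terminal fragments exist), sites are found overlap-allowed on the given
strand (equivalent to double-strand search in these sequence contexts),
and partial digestion is modeled as an independent per-site cut
probability (default 1.0) rather than kinetics. `fraction_high_MW` is the
fraction of bp mass in fragments above a threshold (default 10 kb);
a 50/50 blocky canonical/TTTAAGG array with ~500-unit blocks leaves
roughly half the mass undigested, the *C. circinalis*-like pattern.
Methylation-dependent digestion (McrBC) is out of scope: it requires two
half-sites at variable spacing and methylation states the simulator does
not model.

## Association statistics

Pearson and Spearman (average ranks for ties) correlations are computed
per variable pair on pairwise-complete cases over a species table
(abundance Mb/1C, GP, SNV count, genome size, chromosome and telocentric
counts per 2n); |r| >= 0.7 (inclusive) is flagged a strong relationship.
P-values use the t-approximation (Pearson) and large-sample approximation
(Spearman); no multiple-testing correction is applied. `fold_range` is
the max/min ratio of positive abundances. The underlying correlation
routines are scipy.stats; the test suite checks them against independent
closed-form implementations.

## Synthetic data: what it emulates and what it does not

The simulator emulates genome skimming of a genome containing telomeric
arrays: iid background sequence at a stated GC (default 0.40), arrays of
controlled variant composition placed without overlap, uniform read
starts, uniform strand, iid substitution errors, Phred+33 qualities.
Defaults follow the skimming setting the pipeline targets: 150-bp
single-end reads, error-free unless stated, all bases Q=37 (a "mixed"
quality model degrades a 20% tail to Q=2 on half the reads solely to
exercise the quality filter). Interspersion is `iid` (independent unit
draws) or `blocky` (geometric block lengths with a stated mean;
successive blocks differ in motif so run lengths match the nominal mean —
exact for symmetric two-motif mixtures, approximate otherwise). Every
artifact carries exact truth: realized unit counts, telomeric bp, true GP,
and per-read origin labels (telomeric when the origin interval overlaps an
array by >= 60% of read length).

Not modeled: indels (the classifier is gap-free), position- or
GC-dependent error/coverage biases, methylation and chromatin, real
repeat-landscape complexity (other satellites, transposons carrying
telomere-like k-mers), or full multi-Gb genome scale. Passing tests
therefore demonstrate the correctness of the rules and estimators under
the stated error model, not robustness to every artifact of real
libraries. Simulation sizes in the tests and acceptance script (genomes
≤ 1.4 Mb, 10⁵ reads, arrays ≤ 2 x 10⁵ units) were chosen as the smallest
scales at which binomial/multinomial sampling error is far smaller than
the tolerances being checked.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; reported GP and Mb/1C are
  full precision internally, rendered to 2 decimals in reports,
  correlations to 5 decimals.
- Quality boundary: pass at exactly 90% of bases above Phred 30.
- Classifier tie-breaks (identity, then G-strand, then lower frame) and
  the leftmost-run rule make decisions deterministic.
- The mapping stringency of 80% is interpreted as identity over the
  accepted run; per-unit mismatch cap 1.
- Both raw-total and passing-total read counts are carried so GP can be
  recomputed under either denominator convention; mates of a pair are
  counted independently.
- Single default seed 20221011 for bundled demos; every generator takes
  an explicit seed and all stage outputs are byte-identical given seeds.
- Degenerate inputs: reads shorter than 7 x min_consecutive_units are
  rejected before scanning; empty quality strings fail the filter;
  zero-coverage pileups return an empty report with a warning; zero
  variance makes correlations an explicit error rather than NaN.

## Known limitations

GP is a read-count proxy: it inherits length-uniformity and
library-representation assumptions. The classifier's acceptance boundary
(runs of >= 8 units covering >= 60% of the read) differs slightly from the
truth-label geometry (>= 60% interval overlap), so estimated GP sits a few
hundredths of a percentage point below the label fraction for reads
straddling array edges; both conventions are recorded. The spectrum
assigns windows to the closest listed motif, so unlisted multi-substitution
variants inflate their nearest listed neighbours unless added as extras.
TaqI site genesis in variant-rich arrays is not derivable from the four
major variants alone; the digestion module only reports sites present in
the sequences it is given.
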