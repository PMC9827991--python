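# telospect

Quantification of telomeric tandem repeats from genome-skimming reads:
abundance, intragenomic heterogeneity, variant-motif spectra, in-silico
restriction digestion, and cross-species association statistics.

## What it does, and for whom

Plant telomeres are arrays of the heptamer TTTAGGG. In several lineages
— most dramatically the cycad genus *Cycas* — telomere-like repeats also
form megabase-sized pericentromeric blocks containing abundant variant
heptamers (TTCAGGG > TTTAAGG > TTCAAGG), and the repeat fraction varies
across land plants by four orders of magnitude. Because tandem arrays
collapse in assemblies, these quantities must be measured directly from
unassembled low-coverage shotgun reads. `telospect` is for comparative
(cyto)genomicists who have skimming FASTQ data and a genome-size estimate
and want, per sample:

- **GP and abundance** — reads are classified against a periodic
  reference, by default (TTTAGGG)₁₄ = 98 nt: a read is telomeric iff it
  carries a run of at least 8 consecutive in-frame heptamer units
  (at most 1 mismatch per unit) covering at least 60% of the read at
  identity >= 0.80, on either strand. Genome proportion
  GP = 100 × mapped/passing reads, and absolute abundance
  Mb/1C = (GP/100) × genome size.
- **Heterogeneity (SNV count)** — classified reads are phased into
  in-frame 7-bp windows and piled onto the reference; every non-reference
  base with coverage > 400, count > 40 and frequency > 20% is one SNV
  call, and the number of calls is the heterogeneity metric.
- **Variant spectrum** — each window is assigned to the closest motif
  among the canonical heptamer, all 21 single-substitution variants and
  configurable extras (default TTCAAGG); frequencies are percentages of
  assigned windows, with motifs >= 10% flagged abundant.
- **In-silico digestion** — Tru1I (TTAA), TaqI (TCGA) and HaeIII (GGCC)
  have no site in pure (TTTAGGG)ₙ, while every TTTAAGG unit carries a
  TTAA; fragment-length distributions of heterogeneous arrays therefore
  read out variant interspersion (iid mixtures give geometric spacing
  with mean 7/p bp).
- **Association statistics** — Pearson/Spearman correlation tables over
  species traits (abundance, GP, SNV count, genome size, chromosome and
  telocentric counts), strong-relationship flag at |r| >= 0.7, and the
  max/min fold range of abundances.

A seeded synthetic-data module simulates genomes with telomeric arrays of
controlled variant composition and skimming reads from them, emitting
exact truth tables, so the full pipeline is testable offline. See
`docs/methods.md` for the model details and limitations.

## Worked example

`examples/demo.yaml` describes a 200-kb genome carrying one 500-unit
array that is 70% TTTAGGG / 30% TTCAGGG (3,500 telomeric bp, true
GP 1.75%), skimmed by 20,000 error-free 150-bp reads:

```sh
telospect run-all --config examples/demo.yaml --outdir demo_out
```

`demo_out/abundance.tsv`:

```text
sample     total_reads  passing_reads  mapped_reads  GP_percent  genome_size_Mb  abundance_Mb
synthetic  20000        20000          356           1.78        500.0           8.9
```

356 of 20,000 reads carry a qualifying heptamer run, giving GP = 1.78%
against the constructed truth of 1.75% (within binomial sampling error;
the truth table in `demo_out/genome_truth.tsv` and per-read labels in
`demo_out/read_truth.tsv` let you check this directly — here exactly 356
reads overlap the array by >= 60%). At a genome size of 500 Mb/1C this
is 8.9 Mb of telomeric repeat per haploid genome.

`demo_out/spectrum.tsv` recovers the array composition: TTTAGGG at
68.5% and TTCAGGG at 31.4% of assigned windows, both flagged abundant,
all other motifs below 0.1%. `demo_out/snv.tsv` contains exactly 14
calls — one per reference position congruent to the substituted third
motif position, e.g.:

```text
position  ref_base  alt_base  coverage  count  frequency
2         T         C         520       164    0.3154
9         T         C         523       148    0.2830
```

i.e. a T→C variant at ~30% frequency at every third-of-heptamer
position, and `snv_count = 14` in `demo_out/profile_summary.json` — the
signature of a 30% TTCAGGG mixture. `demo_out/digest.tsv` shows 0 sites
and a single undigested fragment for all three enzymes, as expected for
an array without TTTAAGG units.

Each stage is also available separately (`telospect quantify`,
`profile-variants`, `digest`, `correlate`, `simulate-genome`,
`simulate-reads`) and as library functions (`telospect.classify_read`,
`estimate_abundance`, `count_motifs`, `call_snvs`, `digest`,
`correlation_table`, ...).

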