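"""Seeded generators for genomes with telomeric arrays and genome-skimming reads.

The generators emulate the inputs of a genome-skimming experiment on plants
with long telomeric arrays: a background genome with one or more embedded
tandem arrays of heptamer units (canonical TTTAGGG interspersed with
variant heptamers at controlled proportions), and short single- or
paired-end reads (default 150 bp, Phred+33) with an iid substitution error
model.  Every artifact carries exact construction-time truth (realized
unit counts, telomeric bp, true genome proportion, per-read origin labels)
so downstream recovery is tested against bookkeeping, never against
re-derivation.  All generators are deterministic given a seed.

Interspersion models:

* ``iid`` — each unit drawn independently from the variant proportions;
* ``blocky`` — runs of identical motifs with geometric length (stated mean);
  successive blocks carry different motifs, so realized run lengths match
  the nominal mean.  Exact for a symmetric two-motif mixture; for skewed
  multi-motif mixtures the realized composition is the stationary mix of
  the block chain, close to (not exactly) the nominal proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from telospect.io import FastqRecord
from telospect.telomere_quant import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ArraySpec:
    """A telomeric array: unit count, variant composition and interspersion.

    variant_props maps 7-bp motifs (G-rich strand) to proportions summing
    to 1.  interspersion is "iid" or "blocky"; mean_block_units applies to
    the blocky model only.
    """

    length_units: int
    variant_props: dict[str, float]
    interspersion: str = "iid"
    mean_block_units: float = 100.0

    def __post_init__(self) -> None:
        if self.length_units < 1:
            raise ValueError("length_units must be >= 1")
        if not self.variant_props:
            raise ValueError("variant_props must be nonempty")
        for m, p in self.variant_props.items():
            if len(m) != 7 or set(m) - set("ACGT"):
                raise ValueError(f"motif {m!r} must be a 7-bp ACGT string")
            if not 0 <= p <= 1:
                raise ValueError(f"proportion for {m} out of [0, 1]: {p}")
        s = sum(self.variant_props.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"variant proportions must sum to 1, got {s}")
        if self.interspersion not in ("iid", "blocky"):
            raise ValueError("interspersion must be 'iid' or 'blocky'")
        if self.mean_block_units < 1:
            raise ValueError("mean_block_units must be >= 1")

    @property
    def length_bp(self) -> int:
        return 7 * self.length_units


@dataclass(frozen=True)
class ArrayRealization:
    """A built array with exact construction-time truth."""

    sequence: str
    unit_counts: dict[str, int]

    @property
    def length_units(self) -> int:
        return sum(self.unit_counts.values())


def build_array(spec: ArraySpec, seed: int = 0) -> ArrayRealization:
    """Realize an array on the G-rich strand; exact unit counts are recorded."""
    rng = np.random.default_rng(seed)
    motifs = sorted(spec.variant_props)  # stable order for determinism
    probs = np.array([spec.variant_props[m] for m in motifs])
    probs = probs / probs.sum()
    n = spec.length_units

    if spec.interspersion == "iid" or len(motifs) == 1:
        idx = rng.choice(len(motifs), size=n, p=probs)
    else:
        idx = np.empty(n, dtype=np.int64)
        filled = 0
        prev = -1
        p_geom = min(1.0, 1.0 / spec.mean_block_units)
        while filled < n:
            m = int(rng.choice(len(motifs), p=probs))
            if m == prev:
                continue  # successive blocks differ so run length == block length
            blk = int(rng.geometric(p_geom))
            blk = min(blk, n - filled)
            idx[filled : filled + blk] = m
            filled += blk
            prev = m

    counts = {m: int(c) for m, c in zip(motifs, np.bincount(idx, minlength=len(motifs)))}
    seq = "".join(motifs[i] for i in idx)
    return ArrayRealization(sequence=seq, unit_counts=counts)


@dataclass(frozen=True)
class GenomeSpec:
    """A synthetic genome: background sequence with placed telomeric arrays."""

    genome_length_bp: int
    array_placements: tuple[tuple[int, ArraySpec], ...] = ()
    background_gc: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length_bp < 1:
            raise ValueError("genome_length_bp must be >= 1")
        if not 0 <= self.background_gc <= 1:
            raise ValueError("background_gc must be in [0, 1]")
        intervals = []
        for pos, spec in self.array_placements:
            if pos < 0 or pos + spec.length_bp > self.genome_length_bp:
                raise ValueError(f"array at {pos} (+{spec.length_bp} bp) exceeds genome bounds")
            intervals.append((pos, pos + spec.length_bp))
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ValueError(f"array placements overlap: [{s1},{e1}) and [{s2},{e2})")


@dataclass(frozen=True)
class GenomeRealization:
    """A built genome plus exact truth: array intervals, telomeric bp, true GP."""

    record_id: str
    sequence: str
    array_intervals: tuple[tuple[int, int], ...]  # 0-based half-open
    unit_counts: dict[str, int]

    @property
    def telomeric_bp(self) -> int:
        return sum(e - s for s, e in self.array_intervals)

    @property
    def true_gp_percent(self) -> float:
        return 100.0 * self.telomeric_bp / len(self.sequence)

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "record_id": self.record_id,
                "genome_bp": len(self.sequence),
                "telomeric_bp": self.telomeric_bp,
                "true_gp_percent": self.true_gp_percent,
                "array_start": s,
                "array_end": e,
            }
            for s, e in (self.array_intervals or ((-1, -1),))
        ]
        return pd.DataFrame(rows)


def build_genome(spec: GenomeSpec, record_id: str = "synthetic_genome") -> GenomeRealization:
    """Build the genome sequence: iid background at the stated GC, arrays spliced in.

    Telomere-like 7-mers arising by chance in the background are allowed —
    they stress-test classifier specificity.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.background_gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seq = rng.choice(_BASES, size=spec.genome_length_bp, p=p)

    intervals = []
    unit_counts: dict[str, int] = {}
    # deterministic per-array seeds derived from the genome seed
    for k, (pos, aspec) in enumerate(sorted(spec.array_placements)):
        arr = build_array(aspec, seed=int(rng.integers(0, 2**31 - 1)))
        seq[pos : pos + aspec.length_bp] = np.frombuffer(arr.sequence.encode(), dtype="S1")
        intervals.append((pos, pos + aspec.length_bp))
        for m, c in arr.unit_counts.items():
            unit_counts[m] = unit_counts.get(m, 0) + c

    return GenomeRealization(
        record_id=record_id,
        sequence=seq.tobytes().decode("ascii"),
        array_intervals=tuple(intervals),
        unit_counts=unit_counts,
    )


@dataclass(frozen=True)
class ReadSimParams:
    """Read simulation: count, length, substitution error rate, quality model.

    quality_model: "constant" gives Q=37 everywhere (passes the Phred
    filter); "mixed" degrades a 20% tail to Q=2 on half the reads, solely
    to exercise the quality filter.  Errors are iid substitutions; no
    indels (the classifier is gap-free and the analysis targets motif
    composition).
    """

    n_reads: int
    read_length: int = 150
    error_rate: float = 0.0
    paired: bool = False
    quality_model: str = "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.quality_model not in ("constant", "mixed"):
            raise ValueError("quality_model must be 'constant' or 'mixed'")


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    start: int  # 0-based on the genome forward strand
    end: int
    strand: str  # "+" or "-"
    telomeric_overlap_bp: int
    is_telomeric_majority: bool  # overlap >= 60% of read length


def _overlap(start: int, end: int, intervals) -> int:
    return sum(max(0, min(end, e) - max(start, s)) for s, e in intervals)


def simulate_reads(
    genome: GenomeRealization,
    params: ReadSimParams,
    majority_fraction: float = 0.60,
) -> tuple[list[FastqRecord], list[ReadTruth]]:
    """Draw uniform reads from the genome; emit FASTQ records and truth labels.

    Starts are uniform over valid positions, strand uniform.  The truth
    label marks reads whose origin interval overlaps an array by at least
    ``majority_fraction`` of the read length — the classifier's nominal
    target.  Paired mode emits two reads per fragment (mate 2 reverse-
    complemented from the fragment end, insert 350 bp or genome-capped);
    mates are labeled and counted independently downstream.
    """
    L = len(genome.sequence)
    rl = params.read_length
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds genome length {L}")
    rng = np.random.default_rng(params.seed)

    n_frag = params.n_reads // 2 if params.paired else params.n_reads
    if params.paired and params.n_reads % 2:
        raise ValueError("paired mode requires an even n_reads")
    insert = min(350, L)

    reads: list[FastqRecord] = []
    truths: list[ReadTruth] = []

    span = insert if params.paired else rl
    starts = rng.integers(0, L - span + 1, size=n_frag)
    strands = rng.integers(0, 2, size=n_frag)

    def emit(idx: int, start: int, minus: bool) -> None:
        end = start + rl
        frag = genome.sequence[start:end]
        if minus:
            frag = reverse_complement(frag)
        seq = frag
        if params.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hit = rng.random(rl) < params.error_rate
            n_err = int(hit.sum())
            if n_err:
                # substitute with one of the three other bases, uniformly
                orig = arr[hit]
                subs = _BASES.view(np.uint8)[rng.integers(0, 4, size=n_err)]
                clash = subs == orig
                while clash.any():
                    subs[clash] = _BASES.view(np.uint8)[rng.integers(0, 4, size=int(clash.sum()))]
                    clash = subs == orig
                arr[hit] = subs
                seq = arr.tobytes().decode("ascii")
        if params.quality_model == "constant":
            qual = "F" * rl  # Q=37
        else:
            if rng.random() < 0.5:
                tail = max(1, rl // 5)
                qual = "F" * (rl - tail) + "#" * tail  # Q=2 tail
            else:
                qual = "F" * rl
        read_id = f"read_{idx}"
        ov = _overlap(start, end, genome.array_intervals)
        reads.append(FastqRecord(read_id, seq, qual))
        truths.append(
            ReadTruth(
                read_id=read_id,
                start=start,
                end=end,
                strand="-" if minus else "+",
                telomeric_overlap_bp=ov,
                is_telomeric_majority=ov >= majority_fraction * rl,
            )
        )

    idx = 0
    for fstart, fstrand in zip(starts, strands):
        if params.paired:
            emit(idx, int(fstart), minus=bool(fstrand))
            idx += 1
            emit(idx, int(fstart) + insert - rl, minus=not bool(fstrand))
            idx += 1
        else:
            emit(idx, int(fstart), minus=bool(fstrand))
            idx += 1

    return reads, truths


SPECIES_COLUMNS = [
    "species",
    "abundance_Mb_1C",
    "GP_percent",
    "snv_count",
    "genome_size_Mb_1C",
    "chromosome_number_2n",
    "telocentric_count_2n",
]


def make_species_table(specs: list[dict]) -> pd.DataFrame:
    """Assemble a species metadata table matching the association-statistics contract.

    Each spec is a mapping with the SPECIES_COLUMNS keys (missing values
    allowed as None/NaN).  The table round-trips losslessly through TSV.
    """
    if not specs:
        raise ValueError("species spec list must be nonempty")
    df = pd.DataFrame(specs)
    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"species specs missing columns: {missing}")
    return df[SPECIES_COLUMNS].reset_index(drop=True)


def simulate_species_table(n_species: int, rho: float, seed: int = 0) -> pd.DataFrame:
    """Synthetic cross-species table with a planted correlation.

    abundance_Mb_1C and snv_count are drawn from a bivariate normal with
    correlation ``rho`` (shifted/scaled to plausible positive ranges);
    genome size is independent noise; chromosome counts are generated so
    telocentric count tracks chromosome number.  Used to validate that the
    association statistics recover a known effect.
    """
    if not -1 < rho < 1:
        raise ValueError("rho must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0, 0], cov, size=n_species)
    chrom = rng.integers(16, 29, size=n_species)
    telo = np.clip(np.round(chrom * rng.uniform(0.1, 0.9, size=n_species)), 0, chrom)
    return make_species_table(
        [
            {
                "species": f"sp_{i}",
                "abundance_Mb_1C": float(10 + 3 * z[i, 0]),
                "GP_percent": float(np.exp(z[i, 0] / 2) / 10),
                "snv_count": float(50 + 15 * z[i, 1]),
                "genome_size_Mb_1C": float(rng.uniform(300, 30000)),
                "chromosome_number_2n": int(chrom[i]),
                "telocentric_count_2n": int(telo[i]),
            }
            for i in range(n_species)
        ]
    )
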