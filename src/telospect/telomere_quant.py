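"""Read classification against a periodic telomeric reference and abundance estimation.

The estimator works on unassembled genome-skimming reads.  A short periodic
reference — by default 14 tandem copies of the canonical plant telomeric
heptamer TTTAGGG, i.e. a 98-nt sequence — stands in for telomeric arrays of
any length.  A read is *telomeric* when it carries a sufficiently long,
sufficiently clean run of in-frame heptamer units on either strand:

* a **unit match** is an in-frame 7-bp window with at most
  ``max_mismatches_per_unit`` mismatches to the motif (default 1, so any
  single-substitution variant unit such as TTCAGGG still extends a run);
* the read is accepted iff its longest run has at least
  ``min_consecutive_units`` units (default 8), covers at least
  ``min_telomeric_fraction`` of the read (default 60%), and has identity at
  least ``min_identity`` over the run (default 80%).

Genome proportion GP = 100 x mapped / passing reads; absolute abundance in
Mb/1C = (GP/100) x genome size.  Read-count GP approximates base-proportion
GP under uniform read length.

The scan is gap-free: telomeric arrays are indel-poor at the unit level and
the acceptance rules are phrased in whole units and fractions, which makes
every decision exactly reproducible (see the brute-force oracle used in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# base -> code; anything non-ACGT gets 255 and never matches (N counts as mismatch)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class TelomericReference:
    """Periodic reference: ``copies`` tandem repeats of a 7-bp motif."""

    motif: str = "TTTAGGG"
    copies: int = 14
    sequence: str = field(init=False)
    reverse_complement_sequence: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.motif) != 7:
            raise ValueError(f"motif must be 7 bp, got {len(self.motif)}")
        if set(self.motif) - set("ACGT"):
            raise ValueError(f"motif must be ACGT only, got {self.motif!r}")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        object.__setattr__(self, "sequence", self.motif * self.copies)
        object.__setattr__(
            self, "reverse_complement_sequence", reverse_complement(self.motif * self.copies)
        )

    def __len__(self) -> int:
        return 7 * self.copies


def build_reference(motif: str = "TTTAGGG", copies: int = 14) -> TelomericReference:
    """Build the periodic telomeric reference (default (TTTAGGG)_14, 98 nt)."""
    return TelomericReference(motif=motif, copies=copies)


@dataclass(frozen=True)
class ClassifierParams:
    """Acceptance rules for the telomeric read classifier and the quality filter.

    Defaults mirror a stringent mapping setup: >= 60% of the read telomeric,
    >= 8 consecutive units, >= 80% identity; quality pass requires Phred > 30
    over >= 90% of the read.
    """

    min_identity: float = 0.80
    min_telomeric_fraction: float = 0.60
    min_consecutive_units: int = 8
    max_mismatches_per_unit: int = 1
    quality_min_phred: int = 30
    quality_min_fraction: float = 0.90

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_telomeric_fraction", "quality_min_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_consecutive_units < 1:
            raise ValueError("min_consecutive_units must be >= 1")
        if self.max_mismatches_per_unit < 0:
            raise ValueError("max_mismatches_per_unit must be >= 0")


@dataclass(frozen=True)
class TelomereHit:
    """A read accepted as telomeric.

    orientation is "G" when the read as sequenced carries the G-rich motif,
    "C" when its reverse complement does.  frame is the 0-6 offset within
    the read at which the in-frame unit tiling starts.
    """

    read_id: str
    orientation: str
    frame: int
    run_units: int
    telomeric_bases: int
    telomeric_fraction: float
    identity: float


def quality_filter(qualities: str, params: ClassifierParams | None = None) -> bool:
    """Pass iff the fraction of bases with Phred > quality_min_phred is >= quality_min_fraction.

    ``qualities`` is the Sanger Phred+33 quality string.  No trimming is
    performed; the read passes or fails whole.  An empty string fails.
    """
    params = params or ClassifierParams()
    n = len(qualities)
    if n == 0:
        return False
    q = np.frombuffer(qualities.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    return float(np.mean(q > params.quality_min_phred)) >= params.quality_min_fraction


def _best_run(mm_units: np.ndarray, max_mm: int) -> tuple[int, int]:
    """Longest run of consecutive unit matches (mm <= max_mm).

    Returns (run_units, total_mismatches_in_run); leftmost run wins ties on
    length, fewest mismatches wins among equal-length leftmost candidates.
    """
    best_len = 0
    best_mm = 0
    cur_len = 0
    cur_mm = 0
    for m in mm_units:
        if m <= max_mm:
            cur_len += 1
            cur_mm += int(m)
            if cur_len > best_len or (cur_len == best_len and cur_mm < best_mm):
                best_len = cur_len
                best_mm = cur_mm
        else:
            cur_len = 0
            cur_mm = 0
    return best_len, best_mm


def classify_read(
    read: str,
    ref: TelomericReference | None = None,
    params: ClassifierParams | None = None,
    read_id: str = "",
) -> TelomereHit | None:
    """Classify one read; return a TelomereHit or None.

    Gap-free scan over both orientations and all 7 frames.  Among
    orientation x frame candidates that satisfy all three acceptance rules
    the best is chosen by maximal run_units, ties broken by higher identity,
    then G-strand over C-strand, then lower frame.

    Reads shorter than 7 x min_consecutive_units cannot contain a qualifying
    run and return None.
    """
    ref = ref or build_reference()
    params = params or ClassifierParams()
    n = len(read)
    if n < 7 * params.min_consecutive_units:
        return None

    motif_enc = _encode(ref.motif)
    best: tuple | None = None  # sort key: (run, identity, strand_pref, -frame)

    for orientation, seq in (("G", read), ("C", reverse_complement(read))):
        enc = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(enc, 7)
        mm = np.count_nonzero(windows != motif_enc, axis=1)  # mm[w] for every start w
        for frame in range(7):
            units = mm[frame::7]
            if units.size == 0:
                continue
            run, run_mm = _best_run(units, params.max_mismatches_per_unit)
            if run < params.min_consecutive_units:
                continue
            bases = 7 * run
            fraction = bases / n
            identity = (bases - run_mm) / bases
            if fraction < params.min_telomeric_fraction or identity < params.min_identity:
                continue
            key = (run, identity, orientation == "G", -frame)
            if best is None or key > best[0]:
                best = (
                    key,
                    TelomereHit(
                        read_id=read_id,
                        orientation=orientation,
                        frame=frame,
                        run_units=run,
                        telomeric_bases=bases,
                        telomeric_fraction=fraction,
                        identity=identity,
                    ),
                )
    return None if best is None else best[1]


@dataclass(frozen=True)
class AbundanceEstimate:
    """Per-sample telomeric abundance: GP (%) and absolute Mb/1C."""

    total_reads: int
    passing_reads: int
    mapped_reads: int
    GP: float
    genome_size_Mb_1C: float
    abundance_Mb_1C: float


def estimate_abundance(
    mapped_reads: int,
    passing_reads: int,
    genome_size_Mb_1C: float,
    total_reads: int | None = None,
) -> AbundanceEstimate:
    """GP = 100 x mapped/passing; abundance = (GP/100) x genome size (Mb/1C).

    ``passing_reads`` is the post-quality-filter denominator; the raw total
    is carried alongside when supplied.
    """
    if passing_reads <= 0:
        raise ValueError("passing_reads must be > 0 (no reads after quality filtering)")
    if genome_size_Mb_1C <= 0:
        raise ValueError("genome_size_Mb_1C must be > 0")
    if mapped_reads < 0 or mapped_reads > passing_reads:
        raise ValueError("mapped_reads must be in [0, passing_reads]")
    gp = 100.0 * mapped_reads / passing_reads
    return AbundanceEstimate(
        total_reads=passing_reads if total_reads is None else total_reads,
        passing_reads=passing_reads,
        mapped_reads=mapped_reads,
        GP=gp,
        genome_size_Mb_1C=genome_size_Mb_1C,
        abundance_Mb_1C=(gp / 100.0) * genome_size_Mb_1C,
    )
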