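"""Intragenomic heterogeneity of telomeric arrays: variant spectra and SNV calls.

Works downstream of the read classifier.  Accepted reads are oriented to
the G-rich strand and partitioned into in-frame, non-overlapping 7-bp
windows ("phasing").  Two measurements follow:

* **variant spectrum** — every window is assigned to the closest motif in a
  list containing the canonical heptamer, all 21 motifs differing from it
  by a single substitution, and configurable multi-substitution extras
  (default TTCAAGG, the double mutant seen at high proportion in *Cycas*).
  Frequencies are percentages of assigned windows; motifs at >= 10%
  frequency are flagged abundant.

* **SNV report** — windows are tiled onto the periodic reference (wrapping
  circularly) to form a per-position pileup; each non-reference base
  exceeding coverage, count and frequency thresholds (defaults 400 / 40 /
  20%) yields one call.  The total number of calls is the heterogeneity
  metric.  Only the G-rich strand is profiled.

Non-overlapping in-frame windows make spectrum frequencies sum to 100%;
phase-locking windows to the unit frame means a variant at array proportion
p surfaces both as a spectrum motif at ~p and as SNV calls at ~p frequency
at the congruent reference positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from telospect.telomere_quant import (
    ClassifierParams,
    TelomereHit,
    TelomericReference,
    classify_read,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class VariantList:
    """Canonical motif + the 21 single-substitution heptamers + extras."""

    canonical: str
    single_sub_variants: tuple[str, ...]
    extra_variants: tuple[str, ...]

    @property
    def full_list(self) -> tuple[str, ...]:
        return (self.canonical,) + self.single_sub_variants + self.extra_variants

    def __len__(self) -> int:
        return len(self.full_list)


def enumerate_variants(canonical: str = "TTTAGGG", extras: tuple[str, ...] = ("TTCAAGG",)) -> VariantList:
    """All 21 motifs at Hamming distance 1 from the canonical 7-mer, plus extras.

    Single-substitution variants are ordered by position then alternative
    base (A<C<G<T).  Extras must be 7-mers at Hamming distance >= 2 (a
    distance-1 extra duplicates a single-substitution class) and are
    appended in the given order.
    """
    if len(canonical) != 7 or set(canonical) - set(_BASES):
        raise ValueError(f"canonical must be a 7-bp ACGT motif, got {canonical!r}")
    singles = []
    for pos in range(7):
        for base in _BASES:
            if base != canonical[pos]:
                singles.append(canonical[:pos] + base + canonical[pos + 1 :])
    seen = set(singles) | {canonical}
    cleaned = []
    for m in extras:
        if len(m) != 7 or set(m) - set(_BASES):
            raise ValueError(f"extra motif must be a 7-bp ACGT motif, got {m!r}")
        if _hamming(m, canonical) <= 1:
            raise ValueError(
                f"extra motif {m} is within Hamming distance 1 of the canonical; "
                "already covered by the single-substitution list"
            )
        if m in seen:
            raise ValueError(f"duplicate extra motif {m}")
        seen.add(m)
        cleaned.append(m)
    return VariantList(
        canonical=canonical,
        single_sub_variants=tuple(singles),
        extra_variants=tuple(cleaned),
    )


@dataclass(frozen=True)
class PhasedRead:
    """A read oriented to the G-rich strand and cut into in-frame 7-bp windows."""

    read_id: str
    orientation: str
    frame: int
    windows: tuple[str, ...]


def phase_read(
    read: str,
    canonical: str = "TTTAGGG",
    hit: TelomereHit | None = None,
    read_id: str = "",
) -> PhasedRead:
    """Orient a classified read to the G-rich strand and window it in frame.

    When the classifier's TelomereHit is supplied its orientation/frame are
    reused; otherwise both are redetermined by brute force over the 2 x 7
    orientation/frame grid, choosing the maximal count of exact-canonical
    windows (ties: fewest total mismatches, then G-strand, then lower
    frame).  Leading/trailing partial windows are discarded.
    """
    if hit is not None:
        orientation, frame = hit.orientation, hit.frame
    else:
        best = None
        for orientation_cand, seq in (("G", read), ("C", reverse_complement(read))):
            for frame_cand in range(7):
                wins = [
                    seq[s : s + 7]
                    for s in range(frame_cand, len(seq) - 6, 7)
                ]
                exact = sum(w == canonical for w in wins)
                mm = sum(_hamming(w, canonical) for w in wins)
                key = (exact, -mm, orientation_cand == "G", -frame_cand)
                if best is None or key > best[0]:
                    best = (key, orientation_cand, frame_cand)
        assert best is not None
        _, orientation, frame = best
    seq = read if orientation == "G" else reverse_complement(read)
    windows = tuple(seq[s : s + 7] for s in range(frame, len(seq) - 6, 7))
    return PhasedRead(read_id=read_id, orientation=orientation, frame=frame, windows=windows)


def classify_and_phase(
    reads,
    ref: TelomericReference,
    params: ClassifierParams | None = None,
) -> list[PhasedRead]:
    """Convenience: classify an iterable of (read_id, sequence) and phase the hits."""
    out = []
    for read_id, seq in reads:
        hit = classify_read(seq, ref, params, read_id=read_id)
        if hit is not None:
            out.append(phase_read(seq, ref.motif, hit=hit, read_id=read_id))
    return out


@dataclass(frozen=True)
class VariantSpectrum:
    """Motif counts/frequencies over the full variant list; >=10% flagged abundant."""

    counts: dict[str, int]
    frequencies: dict[str, float]
    abundant: dict[str, bool]
    assigned_windows: int
    unassigned_windows: int


def count_motifs(
    phased_reads: list[PhasedRead],
    variants: VariantList,
    abundant_threshold: float = 10.0,
    max_mismatches: int = 2,
) -> VariantSpectrum:
    """Assign every window to its closest listed motif and tally the spectrum.

    A window goes to the motif in the full list with fewest mismatches
    (ties: canonical first, then list order); windows farther than
    ``max_mismatches`` from every listed motif count as unassigned.
    Frequencies are percentages of assigned windows.
    """
    window_counts: dict[str, int] = {}
    for pr in phased_reads:
        for w in pr.windows:
            window_counts[w] = window_counts.get(w, 0) + 1
    if not window_counts:
        raise ValueError("no windows to count (empty phased read set)")

    motifs = variants.full_list
    counts = {m: 0 for m in motifs}
    unassigned = 0
    for w, n in window_counts.items():
        best_m = None
        best_d = 8
        for m in motifs:  # list order encodes the tie-break (canonical first)
            d = _hamming(w, m)
            if d < best_d:
                best_d = d
                best_m = m
        if best_m is None or best_d > max_mismatches:
            unassigned += n
        else:
            counts[best_m] += n
    assigned = sum(counts.values())
    freqs = {m: (100.0 * c / assigned if assigned else 0.0) for m, c in counts.items()}
    return VariantSpectrum(
        counts=counts,
        frequencies=freqs,
        abundant={m: f >= abundant_threshold for m, f in freqs.items()},
        assigned_windows=assigned,
        unassigned_windows=unassigned,
    )


@dataclass(frozen=True)
class SNVCallParams:
    """Thresholds for SNV calling on the periodic reference (all strict >)."""

    min_coverage: int = 400
    min_variant_count: int = 40
    min_frequency: float = 0.20

    def __post_init__(self) -> None:
        if self.min_coverage <= 0 or self.min_variant_count <= 0 or self.min_frequency <= 0:
            raise ValueError("all SNV thresholds must be positive")


@dataclass(frozen=True)
class SNVCall:
    position: int  # 0-based on the linear reference
    ref_base: str
    alt_base: str
    coverage: int
    variant_count: int
    frequency: float


@dataclass(frozen=True)
class SNVReport:
    """Per-position variant calls; snv_count is the heterogeneity metric."""

    calls: tuple[SNVCall, ...]
    snv_count: int
    mean_coverage: float
    coverage_cv: float  # coefficient of variation of per-position coverage (uniformity QC)
    calls_by_motif_position: dict[tuple[int, str], int] = field(default_factory=dict)


def call_snvs(
    phased_reads: list[PhasedRead],
    ref: TelomericReference,
    params: SNVCallParams | None = None,
) -> SNVReport:
    """Pileup phased reads onto the linear reference and call SNVs.

    Each read's complete windows are tiled onto the reference wrapping
    circularly (the reference is periodic, so wrapping avoids edge-coverage
    artifacts).  The anchor unit rotates deterministically with read index
    so reads of any length cover the reference evenly, as reads sampled
    from a long array would; only the modulo-7 congruence of a position is
    biologically meaningful.  A call is made for every (position,
    alternative base) with coverage > min_coverage, count >
    min_variant_count and frequency > min_frequency.  A modulo-7 collapsed
    summary of calls accompanies the linear-coordinate list.
    """
    params = params or SNVCallParams()
    L = len(ref)
    counts = np.zeros((L, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(_BASES)}

    for i, pr in enumerate(phased_reads):
        seq = "".join(pr.windows)
        enc = np.array([base_idx.get(b, -1) for b in seq], dtype=np.int64)
        anchor = 7 * (i % ref.copies)  # rotate in whole units; congruence preserved
        pos = (anchor + np.arange(len(seq), dtype=np.int64)) % L
        keep = enc >= 0  # skip ambiguity codes in the pileup
        np.add.at(counts, (pos[keep], enc[keep]), 1)

    coverage = counts.sum(axis=1)
    total = int(coverage.sum())
    if total == 0:
        logger.warning("SNV pileup has zero coverage everywhere; empty report")
        return SNVReport(calls=(), snv_count=0, mean_coverage=0.0, coverage_cv=0.0)

    mean_cov = float(coverage.mean())
    cov_cv = float(coverage.std() / mean_cov) if mean_cov > 0 else 0.0

    calls = []
    by_motif_pos: dict[tuple[int, str], int] = {}
    for p in range(L):
        cov = int(coverage[p])
        if cov <= params.min_coverage:
            continue
        ref_base = ref.sequence[p]
        for b in _BASES:
            if b == ref_base:
                continue
            c = int(counts[p, base_idx[b]])
            freq = c / cov
            if c > params.min_variant_count and freq > params.min_frequency:
                calls.append(
                    SNVCall(
                        position=p,
                        ref_base=ref_base,
                        alt_base=b,
                        coverage=cov,
                        variant_count=c,
                        frequency=freq,
                    )
                )
                key = (p % 7, b)
                by_motif_pos[key] = by_motif_pos.get(key, 0) + 1

    return SNVReport(
        calls=tuple(calls),
        snv_count=len(calls),
        mean_coverage=mean_cov,
        coverage_cv=cov_cv,
        calls_by_motif_position=by_motif_pos,
    )
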