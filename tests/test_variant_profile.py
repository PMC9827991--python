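"""Variant enumeration, read phasing, motif spectra and SNV calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import hamming

from telospect import (
    ArraySpec,
    SNVCallParams,
    build_array,
    build_reference,
    call_snvs,
    count_motifs,
    enumerate_variants,
    phase_read,
)
from telospect.telomere_quant import reverse_complement
from telospect.variant_profile import PhasedRead


def phased_from_array(units, proportions, n_reads, read_len=147, seed=0, canonical="TTTAGGG"):
    """Phase reads drawn fully inside an iid mixture array."""
    arr = build_array(ArraySpec(units, proportions, "iid"), seed=seed)
    rng = np.random.default_rng(seed + 1)
    starts = rng.integers(0, len(arr.sequence) - read_len + 1, size=n_reads)
    phased = [
        phase_read(arr.sequence[s : s + read_len], canonical, read_id=f"r{i}")
        for i, s in enumerate(starts)
    ]
    return arr, phased


class TestEnumerateVariants:
    def test_lists_all_21_single_substitutions(self):
        vl = enumerate_variants("TTTAGGG")
        assert len(vl.single_sub_variants) == 21
        for m in ("TTCAGGG", "TTAAGGG", "TTTAAGG"):
            assert m in vl.single_sub_variants
        assert all(hamming(m, "TTTAGGG") == 1 for m in vl.single_sub_variants)
        assert len(set(vl.full_list)) == len(vl.full_list)

    def test_default_extra_is_the_double_mutant(self):
        vl = enumerate_variants()
        assert vl.extra_variants == ("TTCAAGG",)
        assert "TTCAAGG" not in vl.single_sub_variants
        assert len(vl.full_list) == 23  # canonical + 21 + TTCAAGG

    @given(
        canonical=st.text(alphabet="ACGT", min_size=7, max_size=7),
    )
    @settings(deadline=None, max_examples=50)
    def test_any_canonical_gives_21_variants(self, canonical):
        vl = enumerate_variants(canonical, extras=())
        assert len(vl.single_sub_variants) == 21

    def test_distance_one_extra_rejected(self):
        with pytest.raises(ValueError):
            enumerate_variants("TTTAGGG", extras=("TTCAGGG",))

    def test_deterministic_order(self):
        vl = enumerate_variants("TTTAGGG", extras=())
        # by position then base A<C<G<T
        assert vl.single_sub_variants[:3] == ("ATTAGGG", "CTTAGGG", "GTTAGGG")


class TestPhaseRead:
    def test_in_frame_read(self):
        pr = phase_read("TTTAGGG" * 16)
        assert pr.frame == 0 and len(pr.windows) == 16
        assert set(pr.windows) == {"TTTAGGG"}

    def test_rotated_read_recovers_frame(self):
        period = "TTTAGGG" * 20
        read = period[3 : 3 + 112]  # 112-bp read starting mid-unit
        pr = phase_read(read)
        assert len(pr.windows) == 15
        assert set(pr.windows) == {"TTTAGGG"}

    def test_c_strand_read_is_oriented_first(self):
        pr = phase_read("CCCTAAA" * 16)
        assert pr.orientation == "C"
        assert set(pr.windows) == {"TTTAGGG"}

    def test_brute_force_frame_choice_matches_all_rotations(self):
        period = "TTTAGGG" * 30
        for rot in range(7):
            read = period[rot : rot + 120]
            pr = phase_read(read)
            exact = sum(w == "TTTAGGG" for w in pr.windows)
            # brute force: best achievable exact-window count over 2x7 grid
            best = 0
            for seq in (read, reverse_complement(read)):
                for f in range(7):
                    wins = [seq[s : s + 7] for s in range(f, len(seq) - 6, 7)]
                    best = max(best, sum(w == "TTTAGGG" for w in wins))
            assert exact == best


class TestCountMotifs:
    def test_pure_canonical_spectrum(self):
        _, phased = phased_from_array(2000, {"TTTAGGG": 1.0}, n_reads=200)
        sp = count_motifs(phased, enumerate_variants())
        assert sp.frequencies["TTTAGGG"] == pytest.approx(100.0)
        assert sum(sp.abundant.values()) == 1

    def test_70_30_mixture_recovered_within_three_sd(self):
        arr, phased = phased_from_array(
            20_000, {"TTTAGGG": 0.7, "TTCAGGG": 0.3}, n_reads=3000, seed=5
        )
        sp = count_motifs(phased, enumerate_variants())
        truth = 100 * arr.unit_counts["TTCAGGG"] / arr.length_units
        n = sp.assigned_windows
        sd = 100 * math.sqrt(0.3 * 0.7 / n)
        # windows resample array positions, so allow extra slack over pure multinomial
        assert abs(sp.frequencies["TTCAGGG"] - truth) <= max(3 * sd, 1.0)
        assert sp.abundant["TTTAGGG"] and sp.abundant["TTCAGGG"]

    def test_cycas_like_mixture_ranks_ttcaggg_second(self):
        props = {"TTTAGGG": 0.55, "TTCAGGG": 0.27, "TTTAAGG": 0.12, "TTCAAGG": 0.06}
        _, phased = phased_from_array(30_000, props, n_reads=4000, seed=8)
        sp = count_motifs(phased, enumerate_variants())
        ranked = sorted(sp.frequencies, key=sp.frequencies.get, reverse=True)
        assert ranked[0] == "TTTAGGG" and ranked[1] == "TTCAGGG"
        assert 22 <= sp.frequencies["TTCAGGG"] <= 31

    def test_frequencies_sum_to_100(self):
        _, phased = phased_from_array(
            5000, {"TTTAGGG": 0.6, "TTCAGGG": 0.4}, n_reads=500, seed=2
        )
        sp = count_motifs(phased, enumerate_variants())
        assert sum(sp.frequencies.values()) == pytest.approx(100.0, abs=1e-6)

    def test_invariant_to_read_order_and_batching(self):
        _, phased = phased_from_array(
            5000, {"TTTAGGG": 0.8, "TTCAGGG": 0.2}, n_reads=400, seed=3
        )
        vl = enumerate_variants()
        sp1 = count_motifs(phased, vl)
        sp2 = count_motifs(list(reversed(phased)), vl)
        assert sp1.counts == sp2.counts
        # splitting into batches and summing counts gives the same tally
        half = len(phased) // 2
        a = count_motifs(phased[:half], vl)
        b = count_motifs(phased[half:], vl)
        assert {m: a.counts[m] + b.counts[m] for m in sp1.counts} == sp1.counts

    def test_far_windows_are_unassigned(self):
        pr = PhasedRead("x", "G", 0, ("AAAAAAA",) * 5 + ("TTTAGGG",) * 5)
        sp = count_motifs([pr], enumerate_variants())
        assert sp.unassigned_windows == 5
        assert sp.assigned_windows == 5

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            count_motifs([], enumerate_variants())


class TestCallSnvs:
    def test_homogeneous_reads_give_zero_snvs(self, ref):
        _, phased = phased_from_array(5000, {"TTTAGGG": 1.0}, n_reads=7000, seed=4)
        report = call_snvs(phased, ref)
        assert report.snv_count == 0
        assert report.coverage_cv < 0.2  # pileup is even

    def test_30pct_variant_mixture_calls_all_congruent_positions(self, ref):
        _, phased = phased_from_array(
            30_000, {"TTTAGGG": 0.7, "TTCAGGG": 0.3}, n_reads=7000, seed=6
        )
        report = call_snvs(phased, ref)
        # TTCAGGG differs at motif position 2 (T->C): 14 congruent sites on 98 nt
        assert report.snv_count == 14
        assert all(c.position % 7 == 2 and c.alt_base == "C" for c in report.calls)
        mean_freq = 100 * np.mean([c.frequency for c in report.calls])
        assert mean_freq == pytest.approx(30.0, abs=2.0)
        assert report.calls_by_motif_position == {(2, "C"): 14}

    def test_low_coverage_gates_all_calls(self, ref):
        _, phased = phased_from_array(
            30_000, {"TTTAGGG": 0.7, "TTCAGGG": 0.3}, n_reads=200, seed=6
        )
        report = call_snvs(phased, ref)
        assert report.mean_coverage < 400
        assert report.snv_count == 0

    def test_snv_count_monotone_in_frequency_threshold(self, ref):
        props = {"TTTAGGG": 0.5, "TTCAGGG": 0.25, "TTTAAGG": 0.15, "TTAAGGG": 0.10}
        _, phased = phased_from_array(30_000, props, n_reads=7000, seed=9)
        counts = [
            call_snvs(phased, ref, SNVCallParams(min_frequency=f)).snv_count
            for f in (0.40, 0.20, 0.05)
        ]
        assert counts == sorted(counts)

    def test_spectrum_snv_agreement(self, ref):
        """A variant abundant at >=20% in the spectrum yields calls at its substituted position."""
        _, phased = phased_from_array(
            30_000, {"TTTAGGG": 0.75, "TTTAAGG": 0.25}, n_reads=7000, seed=10
        )
        sp = count_motifs(phased, enumerate_variants())
        assert sp.frequencies["TTTAAGG"] >= 20
        report = call_snvs(phased, ref)
        # TTTAAGG differs at motif position 4 (G->A)
        assert (4, "A") in report.calls_by_motif_position

    def test_empty_pileup_is_empty_report(self, ref):
        report = call_snvs([], ref)
        assert report.snv_count == 0 and report.calls == ()
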