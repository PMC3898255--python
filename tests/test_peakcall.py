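"""Dominance criterion, binomial test and peak selection."""

import math
from fractions import Fraction

import numpy as np
import pytest

from degmotif.core_io import EndCountTable, GenomeSequences, RegionLabel
from degmotif.peakcall import (
    PeakTestParams,
    binom_point,
    binom_tail,
    call_peaks,
    dominance_fraction,
    extract_windows,
    filter_mirna_sites,
    select_top,
    window_profile,
)

Q = Fraction(1, 21)


def exhaustive_tail(x: int, n: int, q: Fraction) -> float:
    """Independent oracle: exact rational sum of upper-tail point masses."""
    total = Fraction(0)
    for k in range(x, n + 1):
        total += math.comb(n, k) * q**k * (1 - q) ** (n - k)
    return float(total)


class TestBinomTail:
    def test_agrees_with_exhaustive_summation_up_to_n_60(self):
        for n in range(1, 61):
            for x in range(0, n + 1):
                expected = exhaustive_tail(x, n, Q)
                assert abs(binom_tail(x, n, 1 / 21) - expected) < 1e-12

    def test_whole_sample_space(self):
        assert binom_tail(0, 5, 1 / 21) == 1.0

    def test_four_reads_pass_threshold_three_fail(self):
        p4 = binom_tail(4, 4, 1 / 21)
        p3 = binom_tail(3, 3, 1 / 21)
        assert p4 == pytest.approx((1 / 21) ** 4, rel=1e-12)
        assert p3 == pytest.approx((1 / 21) ** 3, rel=1e-12)
        assert p4 < 1e-5 <= p3

    def test_point_mass_never_exceeds_tail(self):
        for n in (1, 5, 20, 40):
            for x in range(n + 1):
                assert binom_point(x, n, 1 / 21) <= binom_tail(x, n, 1 / 21) + 1e-15

    @pytest.mark.parametrize("bad_q", [0.0, 1.0, -0.1])
    def test_q_outside_unit_interval_rejected(self, bad_q):
        with pytest.raises(ValueError):
            binom_tail(1, 2, bad_q)


def _profile(center, around=(), halfwidth=10):
    """WindowProfile with `center` reads at offset 0 and (offset, count) extras."""
    counts = np.zeros(2 * halfwidth + 1, dtype=np.int64)
    counts[halfwidth] = center
    for off, c in around:
        counts[halfwidth + off] = c
    from degmotif.peakcall import WindowProfile

    return WindowProfile(counts, halfwidth)


class TestDominance:
    def test_singleton_peak_is_fully_dominant(self):
        assert dominance_fraction(_profile(9)) == 1.0

    def test_uniform_window(self):
        prof = _profile(1, [(o, 1) for o in range(-10, 11) if o != 0])
        assert dominance_fraction(prof) == pytest.approx(3 / 21)

    def test_boundary_half_is_inclusive(self):
        prof = _profile(5, [(-1, 2), (1, 3), (5, 4), (-7, 6)])
        assert dominance_fraction(prof) == 0.5
        params = PeakTestParams()
        assert dominance_fraction(prof) >= params.dominance_min

    def test_empty_window_is_an_error(self):
        with pytest.raises(ValueError, match="empty window"):
            dominance_fraction(_profile(0))


class TestWindowProfile:
    def test_isolated_pileup(self):
        table = EndCountTable()
        table.add("c1", "+", 100, 9)
        prof = window_profile(table, "c1", "+", 100)
        assert prof.at(0) == 9 and prof.n == 9

    def test_minus_strand_orientation(self):
        table = EndCountTable()
        table.add("c1", "-", 100, 2)
        table.add("c1", "-", 99, 5)  # 1 nt 3' of the end on '-'
        prof = window_profile(table, "c1", "-", 100)
        assert prof.at(+1) == 5 and prof.at(-1) == 0

    def test_chromosome_edge_reads_zero(self):
        table = EndCountTable()
        table.add("c1", "+", 3, 4)
        prof = window_profile(table, "c1", "+", 3)
        assert prof.n == 4
        assert all(prof.at(o) == 0 for o in range(-10, -3))


def _single_gene_annotation():
    from degmotif.core_io import Gene, GenomeAnnotation, Transcript

    tx = Transcript("t1", "g1", "c1", "+", [(0, 1000)], [(0, 1000)])
    return GenomeAnnotation([Gene("g1", "c1", "+", 0, 1000, [tx])])


class TestCallPeaks:
    def test_isolated_four_read_pileup_is_retained(self):
        table = EndCountTable()
        table.add("c1", "+", 500, 4)
        peaks = call_peaks(table, _single_gene_annotation())
        (peak,) = peaks[RegionLabel.CDS]
        assert peak.x == peak.n == 4
        assert peak.dominance == 1.0
        assert peak.p_value == pytest.approx((1 / 21) ** 4, rel=1e-9)

    def test_three_read_pileup_rejected_by_p_value(self):
        table = EndCountTable()
        table.add("c1", "+", 500, 3)
        peaks = call_peaks(table, _single_gene_annotation())
        assert all(not ps for ps in peaks.values())

    def test_uniform_spread_rejected_by_dominance(self):
        table = EndCountTable()
        for off in range(-10, 11):
            table.add("c1", "+", 500 + off, 1)
        peaks = call_peaks(table, _single_gene_annotation())
        assert all(not ps for ps in peaks.values())

    def test_input_order_invariance(self, tmp_path):
        rows = [("c1", "+", 500, 6), ("c1", "+", 300, 4), ("c1", "-", 700, 5)]
        t1, t2 = EndCountTable(), EndCountTable()
        for r in rows:
            t1.add(*r)
        for r in reversed(rows):
            t2.add(*r)
        ann = _single_gene_annotation()
        p1 = call_peaks(t1, ann)
        p2 = call_peaks(t2, ann)
        key = lambda p: (p.chrom, p.strand, p.end_pos, p.x, p.n, p.p_value)
        for region in p1:
            assert [key(p) for p in p1[region]] == [key(p) for p in p2[region]]

    def test_planted_isolated_peaks_all_recovered_over_zero_background(self):
        rng = np.random.default_rng(5)
        table = EndCountTable()
        planted = []
        for i in range(40):
            pos = 30 + i * 25
            height = int(rng.integers(5, 30))
            table.add("c1", "+", pos, height)
            planted.append(pos)
        peaks = call_peaks(table, _single_gene_annotation())
        called = {p.end_pos for ps in peaks.values() for p in ps}
        assert called == set(planted)


class TestMirnaFilter:
    def _peak(self, pos):
        from degmotif.peakcall import Peak

        return Peak("c1", "+", pos, RegionLabel.THREE_UTR, 10, 10, 1.0, 1e-9)

    @pytest.mark.parametrize(
        "peak_pos, tolerance, excluded",
        [(100, 0, True), (101, 0, False), (101, 1, True)],
    )
    def test_tolerance(self, peak_pos, tolerance, excluded):
        peaks = filter_mirna_sites([self._peak(peak_pos)], [("c1", "+", 100)], tolerance)
        assert peaks[0].excluded_mirna is excluded

    def test_flag_does_not_alter_statistics(self):
        peak = self._peak(100)
        before = (peak.p_value, peak.dominance)
        filter_mirna_sites([peak], [("c1", "+", 100)], 0)
        assert (peak.p_value, peak.dominance) == before


class TestSelectTop:
    def _peaks(self, n):
        from degmotif.peakcall import Peak

        return [
            Peak("c1", "+", i, RegionLabel.CDS, x=1000 + (i % 7), n=1200, dominance=1.0,
                 p_value=1e-9)
            for i in range(n)
        ]

    def test_caps_at_top_k_by_abundance(self):
        peaks = self._peaks(1200)
        kept = select_top(peaks)
        assert len(kept) == 1000
        dropped_x = [p.x for p in peaks if p.end_pos not in {k.end_pos for k in kept}]
        assert min(p.x for p in kept) >= max(dropped_x)

    def test_under_cap_keeps_all(self):
        assert len(select_top(self._peaks(999))) == 999

    def test_rank_ties_broken_by_coordinate(self):
        from degmotif.peakcall import Peak

        a = Peak("c1", "+", 50, RegionLabel.CDS, 10, 10, 1.0, 1e-9)
        b = Peak("c1", "+", 20, RegionLabel.CDS, 10, 10, 1.0, 1e-9)
        kept = select_top([a, b], PeakTestParams(top_k=1))
        assert kept[0].end_pos == 20


class TestExtractWindows:
    def _genome(self):
        rng = np.random.default_rng(3)
        return GenomeSequences({"c1": "".join(rng.choice(list("ACGT"), size=300))})

    def _peak(self, pos, strand="+"):
        from degmotif.peakcall import Peak

        return Peak("c1", strand, pos, RegionLabel.CDS, 5, 5, 1.0, 1e-9)

    def test_plus_strand_slice_and_end_character(self):
        genome = self._genome()
        (win,) = extract_windows([self._peak(100)], genome)
        assert win.sequence == genome["c1"][75:125]
        assert len(win.sequence) == 50
        assert win.sequence[25] == genome["c1"][100]  # 26th character = the end

    def test_minus_strand_reverse_complement(self):
        from degmotif.core_io import revcomp

        genome = self._genome()
        (win,) = extract_windows([self._peak(100, "-")], genome)
        assert win.sequence == revcomp(genome["c1"][76:126])
        assert win.sequence[25] == revcomp(genome["c1"][100])

    def test_edge_window_padded_and_flagged(self):
        (win,) = extract_windows([self._peak(10)], self._genome())
        assert win.truncated
        assert win.sequence.startswith("N" * 15)
        assert len(win.sequence) == 50

    def test_missing_chromosome(self):
        with pytest.raises(KeyError):
            extract_windows([self._peak(10)], GenomeSequences({"cX": "ACGT"}))
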