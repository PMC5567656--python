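"""Phase-register consolidation, binomial tail, phase score and the scan."""

import math
from fractions import Fraction

import numpy as np
import pytest

from sncrna import synthetic as syn
from sncrna.core import AlignmentRecord
from sncrna.phasing import (
    PhaseParams, consolidate, merge_called_windows, phase_score,
    phasing_pvalue, scan_windows,
)


def _aln(start, strand, length=21, count=1, target="chr1"):
    return AlignmentRecord(
        read_seq="A" * length, target_id=target, start=start, strand=strand,
        count=count,
    )


def exact_pvalue(j, n, i):
    """Exact rational evaluation of the upper binomial tail."""
    q = Fraction(1, i)
    cdf = sum(
        Fraction(math.comb(n, k)) * q**k * (1 - q) ** (n - k)
        for k in range(j + 1)
    )
    return 1 - cdf


class TestConsolidate:
    def test_plus_read_keeps_leftmost_coordinate(self):
        out = consolidate([_aln(100, "+")], i=21)
        assert out["chr1"] == [(100, 1, "+")]

    def test_minus_read_shifted_by_duplex_overhang(self):
        # minus read occupying 102..122 consolidates to 100
        out = consolidate([_aln(102, "-")], i=21)
        assert out["chr1"] == [(100, 1, "-")]

    def test_other_lengths_excluded(self):
        out = consolidate([_aln(100, "+", length=24)], i=21)
        assert out == {}

    def test_perfect_duplex_partners_share_one_register(self):
        alns = [_aln(100 + k * 21, "+" if k % 2 else "-") for k in range(8)]
        # shift the minus reads so their consolidated position matches
        alns = [
            a if a.strand == "+" else _aln(a.start + 2, "-")
            for a in alns
        ]
        out = consolidate(alns, i=21)
        registers = {pos % 21 for pos, _, _ in out["chr1"]}
        assert len(registers) == 1


class TestPvalue:
    def test_j_equals_n_gives_zero(self):
        assert phasing_pvalue(10, 10, 21) == 0.0

    def test_j_zero_n_one_is_one_over_i(self):
        assert phasing_pvalue(0, 1, 21) == pytest.approx(1 / 21, rel=1e-12)

    @pytest.mark.parametrize("i", [21, 24])
    def test_matches_exact_rational_brute_force(self, i):
        for n in range(0, 61, 5):
            for j in range(0, n + 1, 3):
                assert phasing_pvalue(j, n, i) == pytest.approx(
                    float(exact_pvalue(j, n, i)), abs=1e-12
                )

    def test_strictly_decreasing_in_j(self):
        values = [phasing_pvalue(j, 40, 21) for j in range(0, 41)]
        assert all(a > b or (a == b == 0) for a, b in zip(values, values[1:]))

    def test_inclusive_flag_counts_j_itself(self):
        assert phasing_pvalue(5, 40, 21, inclusive=True) == pytest.approx(
            float(exact_pvalue(4, 40, 21)), abs=1e-12
        )

    def test_large_n_is_finite_and_in_range(self):
        p = phasing_pvalue(5000, 100_000, 21)
        assert 0.0 <= p <= 1.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            phasing_pvalue(5, 4, 21)
        with pytest.raises(ValueError):
            phasing_pvalue(0, 4, 1)


class TestPhaseScore:
    def test_two_occupied_positions_give_zero(self):
        assert phase_score([(100, 3), (121, 2)], i=21) == 0.0

    def test_eight_positions_seven_reads(self):
        registers = [(100 + 21 * k, 1) for k in range(7)] + [(100 + 21 * 7, 0)]
        occupied = [(p, c) for p, c in registers if c > 0]
        # n = 7 occupied, sum k = 7 -> P = 5 * ln 8
        assert phase_score(occupied, i=21) == pytest.approx(5 * math.log(8))

    def test_monotone_in_occupancy_and_reads(self):
        base = [(100 + 21 * k, 1) for k in range(4)]
        more_reads = [(p, c + 1) for p, c in base]
        more_pos = base + [(100 + 21 * 5, 1)]
        p0 = phase_score(base, i=21)
        assert phase_score(more_reads, i=21) > p0
        assert phase_score(more_pos, i=21) > p0


class TestScanWindows:
    def test_planted_register_called_and_reads_reported(self):
        alns, truth = syn.gen_phased_testset(
            1, seed=30, i=21, positions_per_locus=30, background_reads=0
        )
        windows, phasirnas = scan_windows(alns, PhaseParams(i=21))
        assert any(w.passed for w in windows)
        assert {(a.start, a.strand) for a in phasirnas} == truth.phased_keys

    def test_heavy_in_window_background_defeats_phased_fraction(self):
        alns, truth = syn.gen_phased_testset(
            1, seed=31, i=21, positions_per_locus=20, background_reads=4000,
            genome_len=20_000, background_avoids_loci=False,
        )
        windows, _ = scan_windows(alns, PhaseParams(i=21))
        locus = truth.loci[0]
        overlapping = [
            w for w in windows if w.start <= locus[1] and locus[0] <= w.end
        ]
        assert overlapping
        for w in overlapping:
            if not w.passed:
                assert "phased_frac" in w.filters_failed or "p" in w.filters_failed

    def test_null_background_yields_no_bonferroni_calls(self):
        false_positive = 0
        n = 40
        for seed in range(n):
            alns, _ = syn.gen_phased_testset(
                0, seed=500 + seed, i=21, background_reads=500
            )
            windows, _ = scan_windows(alns, PhaseParams(i=21))
            false_positive += any(w.passed for w in windows)
        assert false_positive <= n * 0.05

    def test_sensitivity_unaffected_by_out_of_window_background(self):
        recovered = []
        for bg in (0, 500, 2000):
            alns, truth = syn.gen_phased_testset(
                3, seed=32, i=21, reads_per_pos=1, background_reads=bg
            )
            windows, _ = scan_windows(alns, PhaseParams(i=21))
            called = [w for w in windows if w.passed]
            recovered.append(
                sum(
                    any(w.start <= e and s <= w.end for w in called)
                    for s, e in truth.loci
                )
            )
        assert recovered == [3, 3, 3]

    def test_result_invariant_under_input_order(self):
        alns, _ = syn.gen_phased_testset(2, seed=33, i=21, background_reads=300)
        w1, p1 = scan_windows(alns, PhaseParams(i=21))
        w2, p2 = scan_windows(list(reversed(alns)), PhaseParams(i=21))
        key = lambda w: (w.target, w.start, w.register, w.j, w.n, w.passed)
        assert [key(w) for w in w1] == [key(w) for w in w2]
        assert {(a.start, a.strand) for a in p1} == {(a.start, a.strand) for a in p2}

    def test_strand_bias_filter_rejects_one_sided_loci(self):
        # all phased reads on the plus strand
        alns = [_aln(1000 + 21 * k, "+", count=1) for k in range(20)]
        windows, _ = scan_windows(
            alns, PhaseParams(i=21, max_strand_frac=0.9)
        )
        assert windows and all(not w.passed for w in windows)
        assert all("strand_bias" in w.filters_failed for w in windows)

    def test_merge_overlapping_called_windows(self):
        alns, _ = syn.gen_phased_testset(
            1, seed=34, i=21, positions_per_locus=40, background_reads=0
        )
        windows, _ = scan_windows(alns, PhaseParams(i=21))
        merged = merge_called_windows(windows)
        assert len(merged) == 1
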