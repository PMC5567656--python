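"""Mapper correctness against a brute-force position-scan oracle, and
non-template tail splitting."""

import numpy as np
import pytest

from sncrna.core import ReferenceRecord, revcomp
from sncrna.mapping import (
    MapParams, find_occurrences, find_tailed_occurrences, map_reads,
    split_nontemplate_tail,
)


def brute_force_hits(read, reference, max_mm):
    """Scan every placement, count substitutions directly."""
    hits = []
    if "N" in read:
        return hits
    for start in range(len(reference) - len(read) + 1):
        mm = [
            i for i in range(len(read)) if read[i] != reference[start + i]
        ]
        if len(mm) <= max_mm:
            hits.append((start, mm))
    return hits


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestFindOccurrences:
    def test_exact_substring_hit(self):
        ref = "GGGGGACGTACGTGGGG"
        assert find_occurrences("ACGTACGT", ref, 0) == [(5, [])]

    def test_one_substitution_recorded(self):
        ref = "TTTTACGAACGTTTTT"
        hits = find_occurrences("ACGTACGT", ref, 1)
        assert (4, [3]) in hits

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_equivalence_with_brute_force_on_random_data(self, max_mm):
        rng = np.random.default_rng(100 + max_mm)
        ref = _random_seq(rng, 5000)
        for _ in range(200):
            read = _random_seq(rng, int(rng.integers(15, 31)))
            assert find_occurrences(read, ref, max_mm) == brute_force_hits(
                read, ref, max_mm
            )

    def test_exhaustive_short_reads_on_small_reference(self):
        rng = np.random.default_rng(200)
        ref = _random_seq(rng, 64)
        from itertools import product

        for read in map("".join, product("ACGT", repeat=6)):
            assert find_occurrences(read, ref, 1) == brute_force_hits(read, ref, 1)

    def test_n_containing_reads_never_align(self):
        assert find_occurrences("ACGNACGT", "ACGTACGTACGT", 2) == []


class TestMapReads:
    def test_minus_strand_equals_plus_mapping_of_reverse_complement(self):
        rng = np.random.default_rng(300)
        refseq = _random_seq(rng, 400)
        ref = [ReferenceRecord(record_id="r", sequence=refseq)]
        params = MapParams(max_mismatch=1, strand_mode="both")
        reads = [(_random_seq(rng, 20), 1) for _ in range(50)]
        # plant some true hits on both strands
        reads += [(refseq[37:57], 1), (revcomp(refseq[100:120]), 1)]
        hits = map_reads(reads, ref, params)
        for seq, _ in reads:
            mine = {(h.start, h.strand) for h in hits if h.read_seq == seq}
            plus = {(s + 1, "+") for s, _ in brute_force_hits(seq, refseq, 1)}
            minus = {
                (s + 1, "-") for s, _ in brute_force_hits(revcomp(seq), refseq, 1)
            }
            assert mine == plus | minus

    def test_minus_strand_mismatch_bases_in_read_orientation(self):
        # reference GGG|ACGT|CCC; read is revcomp(ACGT) with one change
        ref = [ReferenceRecord(record_id="r", sequence="GGGACGTCCC")]
        read = "ACGA"  # revcomp = TCGT vs ACGT at ref 4..7? scan both strands
        hits = map_reads([(read, 1)], ref, MapParams(max_mismatch=1))
        for h in hits:
            for pos, read_base, template_base in h.mismatches:
                assert h.read_seq[pos - 1] == read_base
                assert read_base != template_base


class TestTailSplit:
    REF = "GGGGGAACCTTGGACGTGGGG"  # template continues ...GT after pos 13

    def test_nontemplate_suffix_becomes_tail(self):
        # core matches at 6..13, template continuation 'AC' vs tail 'AA'
        read = self.REF[5:13] + "TT"
        res = split_nontemplate_tail(read, self.REF, 6, MapParams(max_mismatch=1))
        assert res is not None
        rec, tail = res
        assert tail == "TT"
        assert rec.mismatches == ()

    def test_templated_suffix_is_not_a_tail(self):
        read = self.REF[5:15]  # entirely templated
        rec, tail = split_nontemplate_tail(
            read, self.REF, 6, MapParams(max_mismatch=1)
        )
        assert tail == ""

    def test_terminal_template_match_stays_in_core(self):
        # template continuation is 'TC'; read suffix 'TA': the templated T
        # belongs to the core, only 'A' is tail
        ref = "AAAACCGGTCGG"  # after core AACCGG (pos 3..8) comes 'TC'
        read = "AACCGG" + "TA"
        res = split_nontemplate_tail(read, ref, 3, MapParams(max_mismatch=1))
        assert res is not None
        rec, tail = res
        assert tail == "A"
        assert rec.core_seq == "AACCGGT"

    def test_tail_longer_than_budget_refused(self):
        read = self.REF[5:13] + "TTT"
        assert (
            split_nontemplate_tail(
                read, self.REF, 6, MapParams(max_mismatch=1, max_tail=2)
            )
            is None
        )

    def test_minimal_tail_split_matches_brute_force(self):
        rng = np.random.default_rng(400)
        ref = _random_seq(rng, 120)
        params = MapParams(max_mismatch=1, max_tail=2)
        for _ in range(300):
            start = int(rng.integers(1, 90))
            core_len = int(rng.integers(15, 25))
            tail_len = int(rng.integers(0, 3))
            read = ref[start - 1: start - 1 + core_len] + _random_seq(rng, tail_len)
            res = split_nontemplate_tail(read, ref, start, params)
            # brute force: smallest t such that each tail base is
            # non-template and the core has <= 1 mismatch
            expected = None
            for t in range(0, params.max_tail + 1):
                core = read[: len(read) - t]
                tail = read[len(read) - t:]
                tmpl = ref[start - 1: start - 1 + len(core)]
                if len(tmpl) < len(core):
                    continue
                mm = sum(a != b for a, b in zip(core, tmpl))
                tail_ok = all(
                    start - 1 + len(core) + k >= len(ref)
                    or tail[k] != ref[start - 1 + len(core) + k]
                    for k in range(t)
                )
                # the split must also be maximal-run: base before the tail
                # (if any in core) must match the template
                boundary_ok = t == len(read) or core[-1] == tmpl[-1] if core else False
                if mm <= params.max_mismatch and tail_ok and boundary_ok:
                    expected = (core, tail)
                    break
            got = None
            if res is not None:
                rec, tail = res
                got = (rec.core_seq, tail)
            assert got == expected, (read, start)


class TestFindTailedOccurrences:
    def test_tailed_read_found_at_planted_locus(self):
        rng = np.random.default_rng(500)
        refseq = _random_seq(rng, 100)
        ref = ReferenceRecord(record_id="r", sequence=refseq)
        core = refseq[20:42]
        tail = "A" if refseq[42] != "A" else "C"
        hits = find_tailed_occurrences(
            core + tail, ref, MapParams(max_mismatch=1, max_tail=2)
        )
        assert any(h.start == 21 and h.tail == tail for h in hits)
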