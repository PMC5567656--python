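"""ncRNA best-hit selection, count apportioning and tRF classes."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sncrna.core import AlignmentRecord, ReadSet, ReferenceRecord
from sncrna.ncrna import (
    NcrnaHit, NcrnaParams, annotate_ncrna, apportion_counts, build_trna_model,
    classify_trf, classify_trf_hits,
)


def _nc(cls, ident, seq):
    return ReferenceRecord(
        record_id=f"ncrna|{cls}|{ident}", sequence=seq, rna_class="ncrna",
        attrs={"field1": cls, "field2": ident},
    )


class TestBestHits:
    RRNA = "GCTAGCATCGGATTGCACAGTCGGCTAAGCTT"
    SNO = "TTACGGATTGCACAGTCGAATACGATCGGTAC"

    def test_single_class_hit(self):
        reads = ReadSet.from_iter([(self.RRNA[4:24], 3)])
        (hit,) = annotate_ncrna(reads, [_nc("rRNA", "r1", self.RRNA)])
        assert hit.classes == ("rRNA",)
        assert hit.h == 1

    def test_equally_well_means_equal_minimal_mismatch(self):
        # read matches rRNA exactly; same read needs 1 mismatch on snoRNA
        read = self.RRNA[8:24]
        sno = self.SNO[:6] + read[:-1] + ("A" if read[-1] != "A" else "C")
        refs = [_nc("rRNA", "r1", self.RRNA), _nc("snoRNA", "s1", sno)]
        (hit,) = annotate_ncrna(ReadSet.from_iter([(read, 1)]), refs)
        assert hit.classes == ("rRNA",)

    def test_two_perfect_classes_give_h_two(self):
        read = self.RRNA[8:24]
        refs = [
            _nc("rRNA", "r1", self.RRNA),
            _nc("tRNA-like", "t1", "AAAA" + read + "GGGG"),
        ]
        (hit,) = annotate_ncrna(ReadSet.from_iter([(read, 1)]), refs)
        assert hit.h == 2


class TestApportioning:
    def test_two_classes_split_evenly(self):
        hit = NcrnaHit("A" * 20, 10, ("rRNA", "snRNA"), 0, ())
        assert apportion_counts([hit]) == {"rRNA": 5.0, "snRNA": 5.0}

    def test_printed_equation_on_two_sequences(self):
        hits = [
            NcrnaHit("A" * 20, 12, ("A", "B", "C"), 0, ()),
            NcrnaHit("C" * 20, 4, ("A",), 0, ()),
        ]
        counts = apportion_counts(hits)
        assert counts == {"A": 8.0, "B": 4.0, "C": 4.0}
        assert sum(counts.values()) == pytest.approx(16.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=1000),
                st.integers(min_value=1, max_value=6),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_conservation_on_random_hit_tables(self, table):
        classes = ["c%d" % k for k in range(6)]
        hits = [
            NcrnaHit("A" * 20, r, tuple(classes[:h]), 0, ())
            for r, h in table
        ]
        counts = apportion_counts(hits)
        assert sum(counts.values()) == pytest.approx(
            sum(r for r, _ in table), abs=1e-9
        )

    def test_matches_exact_rational_arithmetic(self):
        rng = np.random.default_rng(13)
        classes = ["c%d" % k for k in range(8)]
        hits, exact = [], {}
        for _ in range(500):
            r = int(rng.integers(1, 500))
            h = int(rng.integers(1, 9))
            chosen = tuple(sorted(rng.choice(classes, size=h, replace=False)))
            hits.append(NcrnaHit("A" * 20, r, chosen, 0, ()))
            for cls in chosen:
                exact[cls] = exact.get(cls, Fraction(0)) + Fraction(r, h)
        counts = apportion_counts(hits)
        for cls, value in counts.items():
            assert value == pytest.approx(float(exact[cls]), rel=1e-12)


class TestTrnaModel:
    def _record(self, L=76, pad5=0, pad3=0, seq=None):
        if seq is None:
            rng = np.random.default_rng(14)
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=pad5 + L + pad3))
        return ReferenceRecord(
            record_id=f"trna|t1|pad5={pad5}|pad3={pad3}", sequence=seq,
            rna_class="trna",
            attrs={"field1": "t1", "pad5": str(pad5), "pad3": str(pad3)},
        )

    def test_canonical_length_boundaries(self):
        model = build_trna_model(self._record(L=76))
        assert (model.d_loop_end, model.ac_start, model.ac_end, model.tpsi_start) == (
            25, 31, 39, 52
        )

    def test_boundaries_scale_with_length(self):
        model = build_trna_model(self._record(L=72))
        scale = 72 / 76
        assert model.d_loop_end == int(25 * scale + 0.5)
        assert model.tpsi_start == int(52 * scale + 0.5)

    def test_too_short_trna_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            build_trna_model(self._record(L=30))

    def test_missing_trailer_means_no_oligo_t(self):
        model = build_trna_model(self._record(L=76, pad3=0))
        assert model.oligo_t is None


class TestClassifyTrf:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(15)
        mature = "".join("ACGT"[i] for i in rng.integers(0, 4, size=76))
        leader = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20))
        trailer = "AG" + "".join("ACG"[i] for i in rng.integers(0, 3, size=12)) + "TTTT" + "ACGACGACGACG"
        rec = ReferenceRecord(
            record_id="trna|t1|pad5=20|pad3=30",
            sequence=leader + mature + trailer[:30], rna_class="trna",
            attrs={"field1": "t1", "pad5": "20", "pad3": "30"},
        )
        return build_trna_model(rec)

    def _aln(self, model, s, e, tail=""):
        # s, e are mature-relative; build the padded-coordinate alignment
        start = model.pad5 + s
        core = model.sequence[start - 1: model.pad5 + e]
        return AlignmentRecord(
            read_seq=core + tail, target_id="trna|t1|pad5=20|pad3=30",
            start=start, strand="+", tail=tail,
        )

    @pytest.mark.parametrize(
        "s, e, tail, expected",
        [
            (1, 25, "", "5' tRF"),
            (1, 33, "", "5' tR-half"),
            (52, 76, "", "3' tRF"),
            (55, 76, "CCA", "3' CCA-tRF"),
            (33, 76, "", "3' tR-half"),
            (-14, 0, "", "tRNA-leader"),
            (12, 45, "", "misc-tRF"),
        ],
    )
    def test_class_boundaries(self, model, s, e, tail, expected):
        assert classify_trf(self._aln(model, s, e, tail), model) == expected

    def test_trailer_fragment_up_to_oligo_t_is_trf1(self, model):
        assert model.oligo_t == 15
        aln = self._aln(model, 77, 76 + model.oligo_t - 1)
        assert classify_trf(aln, model) == "tRF-1"

    def test_alignment_outside_padded_region_rejected(self, model):
        bad = AlignmentRecord(
            read_seq="A" * 200, target_id="t", start=1, strand="+"
        )
        with pytest.raises(ValueError, match="outside"):
            classify_trf(bad, model)


class TestTrfEndToEnd:
    def test_synthetic_trf_set_class_agreement(self, trna_refs, trf_set):
        from sncrna.synthetic import to_readset

        reads = to_readset(trf_set)
        hits = annotate_ncrna(reads, trna_refs, NcrnaParams(max_mismatch=1))
        assert len(hits) / len(trf_set) >= 0.97
        models = {r.record_id: build_trna_model(r) for r in trna_refs}
        truth = {l.sequence: l.tier for l in trf_set}
        ok = 0
        for h in hits:
            classes = {
                classify_trf(a, models[a.target_id])
                for a in h.alignments if a.target_id in models
            }
            ok += truth[h.read_seq] in classes and len(classes) == 1
        assert ok / len(hits) >= 0.97

    def test_per_class_shares_match_generator_truth(self, trna_refs, trf_set):
        from collections import Counter

        from sncrna.synthetic import to_readset

        hits = annotate_ncrna(to_readset(trf_set), trna_refs)
        models = {r.record_id: build_trna_model(r) for r in trna_refs}
        shares = classify_trf_hits(hits, models)
        truth = Counter()
        for l in trf_set:
            truth[l.tier] += l.count
        total_true = sum(truth.values())
        total_got = sum(shares.values())
        for cls, t in truth.items():
            assert abs(shares.get(cls, 0) / total_got - t / total_true) < 0.03
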