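"""Fractional ncRNA/cDNA annotation and tRNA-derived fragment classes.

Reads left unassigned by the miRNA stage are mapped to a class-tagged
collection of ncRNA/cDNA references.  A sequence matching several
classes equally well (equal minimal mismatch count) is apportioned:
each class receives r_i / h_i where r_i is the sequence's read count
and h_i the number of distinct classes hit equally well, so

    c_class = sum_i r_i / h_i

conserves total annotated reads.

Reads hitting tRNAs are further classified into eight fragment classes:
5' tRF (5' end to D-loop), 5' tR-half (5' end to anticodon loop),
3' tRF (T-psi-C loop to 3' end), 3' CCA-tRF (same, reaching the mature
3' end with a CCA), 3' tR-half (anticodon loop to 3' end), tRF-1
(trailer fragment from the mature 3' end to an oligo-T signal),
tRNA-leader (upstream of the mature 5' end) and misc-tRF.  Loop
boundaries are proportional projections of the canonical 76-nt
cloverleaf (D-loop end 25, anticodon loop 31-39, T-psi-C start 52),
with a +-2 nt anchoring tolerance by default.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import AlignmentRecord, ReadSet, ReferenceRecord
from .mapping import MapParams, map_reads

TRF_CLASSES = (
    "5' tRF", "5' tR-half", "3' tRF", "3' CCA-tRF", "3' tR-half",
    "tRF-1", "tRNA-leader", "misc-tRF",
)

# canonical cloverleaf landmarks on a 76-nt tRNA
_CANONICAL_LEN = 76
_D_LOOP_END = 25
_AC_START = 31
_AC_END = 39
_TPSI_START = 52


@dataclass(frozen=True)
class NcrnaParams:
    max_mismatch: int = 1
    tolerance: int = 2  # tRF boundary anchoring tolerance, nt


@dataclass(frozen=True)
class TrnaModel:
    """Structural model of one tRNA reference with optional genomic flanks."""

    trna_id: str
    sequence: str  # padded sequence: leader + mature + trailer
    pad5: int
    pad3: int
    d_loop_end: int
    ac_start: int
    ac_end: int
    tpsi_start: int
    oligo_t: int | None  # mature-relative 1-based start of first >=4-T run in trailer

    def __post_init__(self) -> None:
        if not 0 < self.d_loop_end < self.ac_start <= self.ac_end < self.tpsi_start <= self.mature_len:
            raise ValueError(f"inconsistent boundaries for {self.trna_id}")

    @property
    def mature_len(self) -> int:
        return len(self.sequence) - self.pad5 - self.pad3

    @property
    def mature_seq(self) -> str:
        return self.sequence[self.pad5: self.pad5 + self.mature_len]


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def build_trna_model(record: ReferenceRecord) -> TrnaModel:
    """Build a :class:`TrnaModel` from a ``>trna|<id>|pad5=<n>|pad3=<n>``
    FASTA record; loop boundaries are scaled from the 76-nt cloverleaf."""
    pad5 = int(record.attrs.get("pad5", 0))
    pad3 = int(record.attrs.get("pad3", 0))
    L = len(record.sequence) - pad5 - pad3
    if L < 40:
        raise ValueError(f"mature tRNA {record.record_id} too short ({L} nt)")
    scale = L / _CANONICAL_LEN
    trailer = record.sequence[len(record.sequence) - pad3:] if pad3 else ""
    oligo_t = trailer.find("TTTT")
    return TrnaModel(
        trna_id=record.attrs.get("field1", record.record_id),
        sequence=record.sequence,
        pad5=pad5,
        pad3=pad3,
        d_loop_end=_round_half_up(_D_LOOP_END * scale),
        ac_start=_round_half_up(_AC_START * scale),
        ac_end=_round_half_up(_AC_END * scale),
        tpsi_start=_round_half_up(_TPSI_START * scale),
        oligo_t=(oligo_t + 1) if oligo_t != -1 else None,
    )


def classify_trf(
    alignment: AlignmentRecord, model: TrnaModel, tolerance: int = 2
) -> str:
    """Classify a tRNA-mapped read into one of the eight tRF classes.

    ``alignment.start`` is 1-based on the padded tRNA sequence; a
    non-empty ``alignment.tail`` of 'CCA' marks an untemplated CCA.
    Coordinates are converted to mature-relative (mature position 1 =
    first mature base; <=0 is the 5' leader, >mature_len the trailer).
    """
    L = model.mature_len
    s = alignment.start - model.pad5
    e = s + alignment.core_len - 1
    if s < 1 - model.pad5 or e > L + model.pad3:
        raise ValueError("alignment outside the padded tRNA region")
    # entirely in the 5' flank, ending close to the mature start
    if e <= 0:
        if 0 - e <= tolerance:
            return "tRNA-leader"
        return "misc-tRF"
    # entirely in the trailer, from the mature 3' end to an oligo-T
    if s > L:
        if (
            s - (L + 1) <= tolerance
            and model.oligo_t is not None
            and e <= L + model.oligo_t + 3  # oligo_t is trailer-relative
        ):
            return "tRF-1"
        return "misc-tRF"
    reaches_end_with_cca = (
        alignment.tail == "CCA" and e >= L - tolerance
    ) or (e >= L - tolerance and alignment.read_seq.endswith("CCA"))
    if s <= 1 + tolerance:  # 5'-anchored
        if e <= model.d_loop_end + tolerance:
            return "5' tRF"
        if model.ac_start - tolerance <= e <= model.ac_end + tolerance:
            return "5' tR-half"
    if e >= L - tolerance or reaches_end_with_cca:  # 3'-anchored
        if s >= model.tpsi_start - tolerance:
            return "3' CCA-tRF" if reaches_end_with_cca else "3' tRF"
        if model.ac_start - tolerance <= s <= model.ac_end + tolerance:
            return "3' tR-half"
    return "misc-tRF"


@dataclass(frozen=True)
class NcrnaHit:
    """Best-hit record for one sequence: equally-best classes and count."""

    read_seq: str
    count: int
    classes: tuple[str, ...]  # distinct classes among best hits, sorted
    best_mismatch: int
    alignments: tuple[AlignmentRecord, ...]

    @property
    def h(self) -> int:
        return len(self.classes)


def _class_of(ref_attrs_id: str, class_by_ref: Mapping[str, str]) -> str:
    return class_by_ref[ref_attrs_id]


def annotate_ncrna(
    reads: ReadSet,
    references: Sequence[ReferenceRecord],
    params: NcrnaParams = NcrnaParams(),
) -> list[NcrnaHit]:
    """Map reads to class-tagged references and record equally-best hits.

    References carry their class in ``rna_class`` ('ncrna' records use
    the first header field as class; 'trna' records are class 'tRNA').
    Mapping is plus-strand only (ncRNA fragments are sense degradation
    products); the best hits of a sequence are those with minimal
    mismatch count and the distinct classes among them define h_i.
    Reads ending in CCA that only align after splitting the
    (post-transcriptional) CCA are retried with the suffix removed
    against tRNA references.
    """
    class_by_ref: dict[str, str] = {}
    for rec in references:
        if rec.rna_class == "ncrna":
            class_by_ref[rec.record_id] = rec.attrs.get("field1", "miscRNA")
        elif rec.rna_class == "trna":
            class_by_ref[rec.record_id] = "tRNA"
        else:
            class_by_ref[rec.record_id] = rec.rna_class or "miscRNA"
    map_params = MapParams(max_mismatch=params.max_mismatch, strand_mode="plus-only")
    trna_refs = [r for r in references if r.rna_class == "trna"]

    hits: list[NcrnaHit] = []
    for seq, count in reads:
        alns = map_reads([(seq, count)], references, map_params)
        if not alns and seq.endswith("CCA") and trna_refs and len(seq) > 3:
            # untemplated CCA on a tRNA fragment: align the core, keep
            # the CCA as a non-template tail
            core_alns = map_reads([(seq[:-3], count)], trna_refs, map_params)
            alns = [
                AlignmentRecord(
                    read_seq=seq, target_id=a.target_id, start=a.start,
                    strand=a.strand, mismatches=a.mismatches, count=count,
                    tail="CCA",
                )
                for a in core_alns
                if a.strand == "+"
            ]
        if not alns:
            continue
        best_mm = min(len(a.mismatches) for a in alns)
        best = [a for a in alns if len(a.mismatches) == best_mm]
        classes = tuple(sorted({_class_of(a.target_id, class_by_ref) for a in best}))
        hits.append(
            NcrnaHit(
                read_seq=seq, count=count, classes=classes,
                best_mismatch=best_mm, alignments=tuple(best),
            )
        )
    return hits


def apportion_counts(hits: Iterable[NcrnaHit]) -> dict[str, float]:
    """Fractional per-class read counts: c_class = sum_i r_i / h_i."""
    counts: dict[str, float] = defaultdict(float)
    for hit in hits:
        share = hit.count / hit.h
        for cls in hit.classes:
            counts[cls] += share
    return dict(counts)


def classify_trf_hits(
    hits: Iterable[NcrnaHit],
    models: Mapping[str, TrnaModel],
    tolerance: int = 2,
) -> dict[str, float]:
    """Apportion tRNA-assigned counts over the eight tRF classes.

    For a sequence whose best hits include tRNA, its tRNA share
    (r_i / h_i) is split uniformly over the distinct tRF classes of its
    tRNA alignments.
    """
    out: dict[str, float] = defaultdict(float)
    for hit in hits:
        if "tRNA" not in hit.classes:
            continue
        share = hit.count / hit.h
        trf_classes = set()
        for aln in hit.alignments:
            model = models.get(aln.target_id)
            if model is not None:
                trf_classes.add(classify_trf(aln, model, tolerance))
        if not trf_classes:
            continue
        for cls in sorted(trf_classes):
            out[cls] += share / len(trf_classes)
    return dict(out)
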