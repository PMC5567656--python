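"""Ungapped k-mismatch alignment against small reference collections.

Reference collections here are small-RNA scale (hairpins, ncRNA
transcripts, piRNA cluster contigs), so the mapper uses a pigeonhole
seed-and-verify strategy per read/reference pair instead of a genome
index: a read with at most ``k`` substitutions must contain at least one
of ``k+1`` equal read segments exactly, so exact ``str.find`` hits on
those segments enumerate all candidate diagonals.

Reads containing N never align (N matches nothing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import AlignmentRecord, ReferenceRecord, revcomp


@dataclass(frozen=True)
class MapParams:
    """Mapping parameters.

    max_mismatch: substitutions tolerated in the aligned core.
    max_tail: longest non-template 3' suffix split off a read (default 2).
    strand_mode: "both" or "plus-only".
    """

    max_mismatch: int = 0
    max_tail: int = 2
    strand_mode: str = "both"

    def __post_init__(self) -> None:
        if self.max_mismatch < 0 or self.max_tail < 0:
            raise ValueError("max_mismatch and max_tail must be >= 0")
        if self.strand_mode not in ("both", "plus-only"):
            raise ValueError(f"bad strand_mode {self.strand_mode!r}")


def _mismatch_positions(query: str, target: str) -> list[int]:
    """0-based positions where two equal-length strings differ."""
    return [i for i, (a, b) in enumerate(zip(query, target)) if a != b]


def find_occurrences(query: str, reference: str, max_mismatch: int) -> list[tuple[int, list[int]]]:
    """All ungapped occurrences of ``query`` in ``reference``.

    Returns (0-based start, 0-based mismatch positions on query) for
    every placement with at most ``max_mismatch`` substitutions.
    """
    L, R = len(query), len(reference)
    if L == 0 or L > R or "N" in query:
        return []
    hits: list[tuple[int, list[int]]] = []
    if max_mismatch == 0:
        p = reference.find(query)
        while p != -1:
            hits.append((p, []))
            p = reference.find(query, p + 1)
        return hits
    # pigeonhole: split query into max_mismatch+1 segments
    n_seg = max_mismatch + 1
    bounds = [round(i * L / n_seg) for i in range(n_seg + 1)]
    candidates: set[int] = set()
    for s in range(n_seg):
        seg = query[bounds[s]: bounds[s + 1]]
        p = reference.find(seg)
        while p != -1:
            start = p - bounds[s]
            if 0 <= start <= R - L:
                candidates.add(start)
            p = reference.find(seg, p + 1)
    for start in sorted(candidates):
        mm = _mismatch_positions(query, reference[start: start + L])
        if len(mm) <= max_mismatch:
            hits.append((start, mm))
    return hits


def map_reads(
    reads: Iterable[tuple[str, int]],
    references: Sequence[ReferenceRecord],
    params: MapParams = MapParams(),
) -> list[AlignmentRecord]:
    """Map collapsed reads to reference sequences.

    Returns every ungapped occurrence with at most ``params.max_mismatch``
    substitutions, on both strands unless ``strand_mode="plus-only"``.
    Mismatches are recorded as (1-based read position, read base,
    template base in read orientation).  No tail splitting is performed
    here; see :func:`split_nontemplate_tail`.
    """
    out: list[AlignmentRecord] = []
    for seq, count in reads:
        for ref in references:
            for start0, mm in find_occurrences(seq, ref.sequence, params.max_mismatch):
                mismatches = tuple(
                    (i + 1, seq[i], ref.sequence[start0 + i]) for i in mm
                )
                out.append(
                    AlignmentRecord(
                        read_seq=seq, target_id=ref.record_id, start=start0 + 1,
                        strand="+", mismatches=mismatches, count=count,
                    )
                )
            if params.strand_mode == "both":
                rc = revcomp(seq)
                for start0, _ in find_occurrences(rc, ref.sequence, params.max_mismatch):
                    template = revcomp(ref.sequence[start0: start0 + len(seq)])
                    mismatches = tuple(
                        (i + 1, seq[i], template[i])
                        for i in _mismatch_positions(seq, template)
                    )
                    out.append(
                        AlignmentRecord(
                            read_seq=seq, target_id=ref.record_id, start=start0 + 1,
                            strand="-", mismatches=mismatches, count=count,
                        )
                    )
    return out


def split_nontemplate_tail(
    read: str, reference: str, start: int, params: MapParams = MapParams(max_mismatch=1)
) -> tuple[AlignmentRecord, str] | None:
    """Split a read aligned at ``start`` (1-based, plus strand) into an
    aligned core and a non-template 3' tail.

    The tail is the maximal run of consecutive 3'-terminal bases that
    each disagree with the template continuation (or fall beyond the
    reference end); a terminal base matching the template stays in the
    core, so the templated explanation is always preferred and the tail
    is the minimal one yielding a valid core.  Returns ``None`` when the
    tail exceeds ``params.max_tail`` or the core violates
    ``params.max_mismatch``.
    """
    if "N" in read:
        return None
    start0 = start - 1
    L = len(read)
    tail_len = 0
    for i in range(L - 1, -1, -1):
        ref_pos = start0 + i
        if ref_pos >= len(reference) or read[i] != reference[ref_pos]:
            tail_len += 1
        else:
            break
    if tail_len > params.max_tail:
        return None
    core = read[: L - tail_len]
    if start0 + len(core) > len(reference) or len(core) == 0:
        return None
    mm = _mismatch_positions(core, reference[start0: start0 + len(core)])
    if len(mm) > params.max_mismatch:
        return None
    mismatches = tuple((i + 1, core[i], reference[start0 + i]) for i in mm)
    tail = read[L - tail_len:]
    rec = AlignmentRecord(
        read_seq=read, target_id="", start=start, strand="+",
        mismatches=mismatches, count=1, tail=tail,
    )
    return rec, tail


def find_tailed_occurrences(
    read: str, ref: ReferenceRecord, params: MapParams
) -> list[AlignmentRecord]:
    """Plus-strand occurrences of a read allowing a non-template 3' tail.

    Candidate diagonals are seeded from the minimal core (the read minus
    ``max_tail`` terminal bases) and each candidate is resolved with
    :func:`split_nontemplate_tail`.
    """
    L = len(read)
    min_core = read[: max(L - params.max_tail, 1)]
    starts = {s for s, _ in find_occurrences(min_core, ref.sequence, params.max_mismatch)}
    out = []
    for start0 in sorted(starts):
        res = split_nontemplate_tail(read, ref.sequence, start0 + 1, params)
        if res is None:
            continue
        rec, _ = res
        out.append(
            AlignmentRecord(
                read_seq=read, target_id=ref.record_id, start=start0 + 1,
                strand="+", mismatches=rec.mismatches, count=1, tail=rec.tail,
            )
        )
    return out
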