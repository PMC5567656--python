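"""Core domain containers shared by all annotation stages.

A small-RNA library is represented as a :class:`ReadSet` of collapsed
unique sequences with integer read counts; every mapping stage produces
:class:`AlignmentRecord` objects (ungapped hits with mismatch positions
and an optional non-template 3' tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and convert RNA U to DNA T."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence {s!r}")
    return s


@dataclass(frozen=True)
class ReadSet:
    """Collapsed unique sequences with read counts.

    Invariants: sequences are unique, non-empty, upper-case over
    {A,C,G,T,N}; all counts are positive; ``total_reads`` equals the sum
    of counts.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seq, count in self.entries:
            if not seq:
                raise ValueError("empty sequence in ReadSet")
            if count <= 0:
                raise ValueError(f"non-positive count {count} for {seq}")
            if set(seq) - VALID_BASES:
                raise ValueError(f"invalid bases in {seq!r}")
            if seq in seen:
                raise ValueError(f"duplicate sequence {seq}")
            seen.add(seq)

    @classmethod
    def from_iter(cls, pairs: Iterable[tuple[str, int]]) -> "ReadSet":
        """Collapse (sequence, count) pairs, merging identical sequences.

        Sequences are normalized (upper-case, U->T); order of first
        appearance is preserved, which keeps downstream output
        deterministic for a given input file.
        """
        counts: dict[str, int] = {}
        for seq, count in pairs:
            s = normalize_sequence(seq)
            if not s:
                raise ValueError("empty sequence")
            counts[s] = counts.get(s, 0) + int(count)
        return cls(tuple(counts.items()))

    @property
    def total_reads(self) -> int:
        return sum(c for _, c in self.entries)

    @property
    def n_sequences(self) -> int:
        return len(self.entries)

    def counts(self) -> dict[str, int]:
        return dict(self.entries)

    def subset(self, sequences: Iterable[str]) -> "ReadSet":
        keep = set(sequences)
        return ReadSet(tuple((s, c) for s, c in self.entries if s in keep))

    def without(self, sequences: Iterable[str]) -> "ReadSet":
        drop = set(sequences)
        return ReadSet(tuple((s, c) for s, c in self.entries if s not in drop))

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AlignmentRecord:
    """Ungapped hit of a read on a reference or genome target.

    ``start`` is the 1-based leftmost coordinate on the target's plus
    strand.  ``read_seq`` is always stored in read orientation (minus
    strand hits are reverse-complemented back).  ``mismatches`` holds
    (1-based position on the read, read base, template base in read
    orientation).  ``tail`` is the non-template 3' suffix of the read
    (empty for plain alignments); it is always a suffix of ``read_seq``.
    """

    read_seq: str
    target_id: str
    start: int
    strand: str
    mismatches: tuple[tuple[int, str, str], ...] = ()
    count: int = 1
    tail: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"coordinate {self.start} < 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tail and not self.read_seq.endswith(self.tail):
            raise ValueError("tail is not a suffix of read_seq")
        for pos, _, _ in self.mismatches:
            if not 1 <= pos <= len(self.read_seq):
                raise ValueError(f"mismatch position {pos} outside read")

    @property
    def core_seq(self) -> str:
        """Aligned portion of the read (tail removed)."""
        return self.read_seq[: len(self.read_seq) - len(self.tail)]

    @property
    def core_len(self) -> int:
        return len(self.read_seq) - len(self.tail)

    @property
    def end(self) -> int:
        """1-based rightmost target coordinate of the aligned core."""
        return self.start + self.core_len - 1

    @property
    def five_prime(self) -> int:
        """Target coordinate of the read's 5' end (strand aware)."""
        return self.start if self.strand == "+" else self.end

    def with_count(self, count: int) -> "AlignmentRecord":
        return replace(self, count=count)


@dataclass(frozen=True)
class ReferenceRecord:
    """Class-tagged reference sequence with optional structural fields.

    ``rna_class`` is a free tag ("rRNA", "tRNA", "hairpin", ...);
    ``attrs`` carries structural annotations parsed from the FASTA
    header (mature coordinates on hairpins, tRNA flank lengths, species
    tags).
    """

    record_id: str
    sequence: str
    rna_class: str = ""
    attrs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty reference sequence {self.record_id}")
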