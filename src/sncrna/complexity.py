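"""Low-complexity read filtering (duster-style).

A read is rejected when a length fraction f > 0.75 (default) of it is
covered by non-overlapping copies of a single short motif (motif length
1-5 nt), or when the fraction of positions drawn from only two specific
nucleotides exceeds the boosted cut-off f' = f + (1-f)*f (0.9375 at the
default f).  Both inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

from .core import ReadSet


@dataclass(frozen=True)
class ComplexityParams:
    f_threshold: float = 0.75
    min_motif: int = 1
    max_motif: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.f_threshold <= 1:
            raise ValueError("f_threshold must be in (0, 1]")
        if self.min_motif < 1 or self.max_motif < self.min_motif:
            raise ValueError("invalid motif length range")

    @property
    def two_nt_threshold(self) -> float:
        """Cut-off f' for the two-nucleotide rule: f + (1-f)*f."""
        f = self.f_threshold
        return f + (1 - f) * f


def _primitive_root(motif: str) -> str:
    """Shortest string whose repetition yields ``motif`` (e.g. 'AA' -> 'A')."""
    L = len(motif)
    for d in range(1, L + 1):
        if L % d == 0 and motif[:d] * (L // d) == motif:
            return motif[:d]
    return motif


def repeat_fraction(seq: str, min_motif: int = 1, max_motif: int = 5) -> float:
    """Largest length fraction of ``seq`` covered by non-overlapping
    occurrences of one motif of length ``min_motif``..``max_motif``.

    Candidate motifs are the substrings of ``seq`` (canonicalized to
    their primitive root); occurrences may appear anywhere in the read,
    tandem repetition is not required.
    """
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    motifs = set()
    for m in range(min_motif, min(max_motif, L) + 1):
        for i in range(L - m + 1):
            motifs.add(_primitive_root(seq[i: i + m]))
    best = 0.0
    for motif in motifs:
        m = len(motif)
        count = 0
        pos = seq.find(motif)
        while pos != -1:
            count += 1
            pos = seq.find(motif, pos + m)  # non-overlapping
        best = max(best, count * m / L)
    return best


def two_nt_fraction(seq: str) -> float:
    """Largest fraction of positions drawn from one unordered base pair."""
    if not seq:
        raise ValueError("empty sequence")
    best = 0.0
    for pair in combinations("ACGT", 2):
        frac = sum(c in pair for c in seq) / len(seq)
        best = max(best, frac)
    # a single-base sequence is trivially covered by any pair containing it
    return best


def is_low_complexity(seq: str, params: ComplexityParams = ComplexityParams()) -> bool:
    """True iff the read fails either the repeat-motif or the
    two-nucleotide composition rule (strict inequalities)."""
    if repeat_fraction(seq, params.min_motif, params.max_motif) > params.f_threshold:
        return True
    return two_nt_fraction(seq) > params.two_nt_threshold


def filter_low_complexity(
    reads: ReadSet, params: ComplexityParams = ComplexityParams()
) -> tuple[ReadSet, ReadSet]:
    """Split a read set into (retained, rejected low-complexity)."""
    kept, rejected = [], []
    for seq, count in reads:
        (rejected if is_low_complexity(seq, params) else kept).append((seq, count))
    return ReadSet(tuple(kept)), ReadSet(tuple(rejected))
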