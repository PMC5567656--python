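"""3' adapter motif inference and trimming.

Small-RNA sequencing reads start with the insert and, given sufficient
read length, run into the 3' adapter.  When the adapter sequence is
unknown it can be inferred as the most frequent k-mer occurring after
the typical miRNA length: with raw read length ``n`` the motif length is
``m = n - 22`` clamped to 6..12, counted at read positions beyond an
ignored 5' prefix (default 22 nt).

Trimming tolerates sequencing errors with a mismatch allowance tied to
motif length (2 mismatches at 12 nt, 1 at 9-11 nt, 0 at 6-8 nt).  A read
lacking the full motif is probed with 3'-truncated motifs (down to 6 nt)
against its very 3' end only.  A final positional-bias pass strips
further 3' positions whose terminal base composition exceeds a bias
threshold (default 0.8), which removes residual adapter bases shared by
most reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .core import ReadSet

MIN_MOTIF = 6
MAX_MOTIF = 12
DEFAULT_IGNORE_5P = 22
DEFAULT_BIAS_THRESHOLD = 0.8
MAX_BIAS_POSITIONS = 5


class AdapterDetectionError(RuntimeError):
    """No adapter motif is observable in the reads."""


@dataclass(frozen=True)
class AdapterModel:
    """Inferred (or user-supplied) 3' adapter motif."""

    motif: str
    read_length: int = 0
    ignore_5p: int = DEFAULT_IGNORE_5P
    bias_threshold: float = DEFAULT_BIAS_THRESHOLD

    def __post_init__(self) -> None:
        if not MIN_MOTIF <= len(self.motif) <= MAX_MOTIF:
            raise ValueError(
                f"motif length {len(self.motif)} outside {MIN_MOTIF}..{MAX_MOTIF}"
            )
        if self.ignore_5p < 0:
            raise ValueError("ignore_5p must be >= 0")
        if not 0 < self.bias_threshold <= 1:
            raise ValueError("bias_threshold must be in (0, 1]")


def infer_motif_length(n: int) -> int:
    """Motif length for raw read length ``n``: n - 22 clamped to 6..12."""
    if n < 1:
        raise ValueError("read length must be >= 1")
    return min(max(n - 22, MIN_MOTIF), MAX_MOTIF)


def mismatch_allowance(motif_len: int) -> int:
    """Mismatches tolerated for a motif: 12 nt -> 2, 9-11 nt -> 1, 6-8 nt -> 0."""
    if not MIN_MOTIF <= motif_len <= MAX_MOTIF:
        raise ValueError(f"motif length {motif_len} outside {MIN_MOTIF}..{MAX_MOTIF}")
    if motif_len == 12:
        return 2
    if motif_len >= 9:
        return 1
    return 0


def detect_adapter(
    reads: ReadSet, ignore_5p: int = DEFAULT_IGNORE_5P,
    bias_threshold: float = DEFAULT_BIAS_THRESHOLD,
) -> AdapterModel:
    """Infer the 3' adapter motif from raw (untrimmed) reads.

    The raw read length ``n`` is the modal length (read-count weighted);
    the motif is the most frequent m-mer starting after position
    ``ignore_5p``, weighted by read count, ties broken lexicographically.
    """
    if len(reads) == 0:
        raise AdapterDetectionError("empty read set")
    length_counts: Counter[int] = Counter()
    for seq, count in reads:
        length_counts[seq.__len__()] += count
    n = max(length_counts, key=lambda length: (length_counts[length], length))
    m = infer_motif_length(n)
    kmer_counts: Counter[str] = Counter()
    for seq, count in reads:
        # m-mers at 1-based start positions > ignore_5p
        for start in range(ignore_5p, len(seq) - m + 1):
            kmer = seq[start: start + m]
            if "N" not in kmer:
                kmer_counts[kmer] += count
    if not kmer_counts:
        raise AdapterDetectionError(
            "no adapter motif observable (reads too short beyond the ignored "
            "5' prefix); consider lowering --trim_ignore_5p"
        )
    motif = min(kmer_counts, key=lambda k: (-kmer_counts[k], k))
    return AdapterModel(
        motif=motif, read_length=n, ignore_5p=ignore_5p, bias_threshold=bias_threshold
    )


def _find_with_mismatches(seq: str, motif: str, allowance: int) -> int:
    """Leftmost occurrence (0-based) of motif in seq with <= allowance
    substitutions, or -1."""
    m = len(motif)
    for start in range(len(seq) - m + 1):
        mm = 0
        for a, b in zip(seq[start: start + m], motif):
            if a != b:
                mm += 1
                if mm > allowance:
                    break
        else:
            return start
    return -1


def _trim_one(seq: str, motif: str) -> str:
    """Trim the adapter from one read; returns the insert ('' if none left)."""
    allowance = mismatch_allowance(len(motif))
    pos = _find_with_mismatches(seq, motif, allowance)
    if pos != -1:
        return seq[:pos]
    # truncate the motif by one 3' base at a time and probe the read's
    # very 3' end only, re-deriving the allowance from the truncated length
    truncated = motif[:-1]
    while len(truncated) >= MIN_MOTIF:
        allowance = mismatch_allowance(len(truncated))
        suffix = seq[-len(truncated):]
        if len(suffix) == len(truncated):
            mm = sum(a != b for a, b in zip(suffix, truncated))
            if mm <= allowance:
                return seq[: len(seq) - len(truncated)]
        truncated = truncated[:-1]
    return seq


def trim_reads(reads: ReadSet, model: AdapterModel) -> ReadSet:
    """Remove the 3' adapter from every read; empty inserts are dropped."""
    pairs = []
    for seq, count in reads:
        trimmed = _trim_one(seq, model.motif)
        if trimmed:
            pairs.append((trimmed, count))
    if not pairs:
        return ReadSet(())
    return ReadSet.from_iter(pairs)


def positional_bias_trim(
    reads: ReadSet,
    bias_threshold: float = DEFAULT_BIAS_THRESHOLD,
    max_positions: int = MAX_BIAS_POSITIONS,
) -> ReadSet:
    """Strip 3'-terminal positions exceeding a nucleotide bias.

    Reads are aligned at their 3' termini; while the most frequent
    terminal base (read-count weighted) exceeds ``bias_threshold``, that
    position is stripped from the reads ending in it.  At most
    ``max_positions`` positions are removed.
    """
    counts = dict(reads.entries)
    for _ in range(max_positions):
        terminal: Counter[str] = Counter()
        for seq, count in counts.items():
            terminal[seq[-1]] += count
        total = sum(terminal.values())
        if total == 0:
            break
        base, top = max(terminal.items(), key=lambda kv: (kv[1], kv[0]))
        if top / total <= bias_threshold:
            break
        new_counts: dict[str, int] = {}
        for seq, count in counts.items():
            stripped = seq[:-1] if seq.endswith(base) else seq
            if stripped:
                new_counts[stripped] = new_counts.get(stripped, 0) + count
        counts = new_counts
        if not counts:
            break
    return ReadSet(tuple(counts.items()))


def infer_and_trim(
    reads: ReadSet,
    motif: str | None = None,
    ignore_5p: int = DEFAULT_IGNORE_5P,
    bias_threshold: float = DEFAULT_BIAS_THRESHOLD,
) -> tuple[ReadSet, AdapterModel]:
    """Full trimming stage: motif inference (unless supplied), motif
    trimming, then positional-bias trimming."""
    if motif is not None:
        model = AdapterModel(
            motif=motif, ignore_5p=ignore_5p, bias_threshold=bias_threshold
        )
    else:
        model = detect_adapter(reads, ignore_5p=ignore_5p, bias_threshold=bias_threshold)
    trimmed = trim_reads(reads, model)
    return positional_bias_trim(trimmed, bias_threshold), model
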