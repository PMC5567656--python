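"""Phased small-RNA (phasiRNA) detection in genome map files.

Plant secondary siRNAs are processed from dsRNA precursors in fixed
phase registers of length i (typically 21 or 24 nt).  After
consolidating reads from both strands into plus-strand registers (a
minus-strand read's leftmost coordinate is shifted by -2 nt, the duplex
3'-overhang geometry), phasing in a sliding window (default 1 kb) is
scored with the upper binomial tail

    p = 1 - sum_{k=0..j} C(n,k) q^k (1-q)^(n-k),    q = 1/i

where n is the total number of length-i reads in the window and j the
number in the modal phase register.  A window is called when p passes a
Bonferroni-corrected critical value (alpha = 0.05 over the analyzed
windows) and survives post-filters: phased fraction >= 50%, phased
reads at >= 5 distinct consolidated positions and no more than 90% of
the phased reads from one strand.  The classical log phase score
P = ln[(1 + sum k)^(n-2)] over eight-cycle windows is provided for
comparison only.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import binom

from .core import AlignmentRecord


@dataclass(frozen=True)
class PhaseParams:
    """Parameters of the sliding-window phasing scan.

    i: phase length in nt (21 or 24 typically; required).
    window: sliding window size in nt (default 1000).
    step: slide step in nt (default window // 2).
    alpha: critical value before Bonferroni correction (default 0.05).
    min_phased_frac: minimal fraction of in-register reads (default 0.5).
    min_loci: minimal distinct consolidated in-register positions (5).
    max_strand_frac: maximal per-strand fraction of phased reads (0.9).
    inclusive_tail: score P(X >= j) instead of the P(X > j) tail.
    """

    i: int
    window: int = 1000
    step: int | None = None
    alpha: float = 0.05
    min_phased_frac: float = 0.5
    min_loci: int = 5
    max_strand_frac: float = 0.9
    inclusive_tail: bool = False

    def __post_init__(self) -> None:
        if self.i < 2:
            raise ValueError("phase length i must be >= 2")
        if self.window < self.i * 8:
            raise ValueError("window must cover at least eight phase cycles")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def effective_step(self) -> int:
        return self.step if self.step is not None else self.window // 2


@dataclass
class PhaseWindow:
    """Evidence for one sliding window on one target."""

    target: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    register: int  # winning register (position mod i)
    j: int  # reads in the winning register
    n: int  # length-i reads in the window
    p: float
    n_loci: int  # distinct consolidated in-register positions
    strand_counts: dict[str, int] = field(default_factory=dict)
    passed: bool = False
    filters_failed: tuple[str, ...] = ()


def consolidate(
    alignments: Iterable[AlignmentRecord], i: int
) -> dict[str, list[tuple[int, int, str]]]:
    """Consolidate length-i reads into plus-strand register positions.

    Returns target -> list of (consolidated position, count, strand).
    A plus-strand read keeps its leftmost coordinate; a minus-strand
    read is shifted to leftmost - 2 so that perfect duplex partners
    (2-nt 3' overhangs) land in the same register.
    """
    out: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for aln in alignments:
        if aln.core_len != i:
            continue
        pos = aln.start if aln.strand == "+" else aln.start - 2
        out[aln.target_id].append((pos, aln.count, aln.strand))
    return dict(out)


def phasing_pvalue(j: int, n: int, i: int, inclusive: bool = False) -> float:
    """Upper binomial tail probability of observing more than j (or at
    least j, with ``inclusive``) of n length-i reads in one register,
    q = 1/i."""
    if not 0 <= j <= n:
        raise ValueError("need 0 <= j <= n")
    if i < 2:
        raise ValueError("phase length i must be >= 2")
    q = 1.0 / i
    return float(binom.sf(j - 1 if inclusive else j, n, q))


def phase_score(window_registers: Sequence[tuple[int, int]], i: int) -> float:
    """Classical log phase score over an eight-cycle window.

    ``window_registers`` holds (consolidated position, read count) for
    the reads in phase; n is the number of occupied phase-cycle
    positions, k their total read count: P = (n - 2) * ln(1 + sum k).
    Returns 0.0 for n < 2 (the exponent convention breaks down).
    """
    occupied = {pos for pos, count in window_registers if count > 0}
    n = len(occupied)
    k_total = sum(count for _, count in window_registers)
    if n < 2:
        return 0.0
    return (n - 2) * math.log1p(k_total)


def scan_windows(
    alignments: Iterable[AlignmentRecord], params: PhaseParams
) -> tuple[list[PhaseWindow], list[AlignmentRecord]]:
    """Slide windows across each target and call phased loci.

    Only windows containing at least one length-i read are analyzed and
    counted for the Bonferroni correction.  For each window the register
    (position mod i) maximizing the read count defines j; the window is
    called when p < alpha / n_windows and all post-filters pass.  The
    length-i reads in the winning register of called windows are
    returned as phasiRNAs (deduplicated); overlapping called windows are
    merged for reporting via :func:`merge_called_windows`.
    """
    alignments = list(alignments)
    per_target = consolidate(alignments, params.i)
    step = params.effective_step

    windows: list[PhaseWindow] = []
    for target in sorted(per_target):
        entries = sorted(per_target[target])
        lo = min(pos for pos, _, _ in entries)
        hi = max(pos for pos, _, _ in entries)
        start = max(1, lo - (lo - 1) % step)
        w = start
        while w <= hi:
            in_win = [e for e in entries if w <= e[0] < w + params.window]
            if in_win:
                by_register: dict[int, int] = defaultdict(int)
                for pos, count, _ in in_win:
                    by_register[pos % params.i] += count
                register = min(
                    by_register, key=lambda r: (-by_register[r], r)
                )
                j = by_register[register]
                n = sum(count for _, count, _ in in_win)
                phased = [e for e in in_win if e[0] % params.i == register]
                strand_counts: dict[str, int] = defaultdict(int)
                for _, count, strand in phased:
                    strand_counts[strand] += count
                windows.append(
                    PhaseWindow(
                        target=target, start=w, end=w + params.window - 1,
                        register=register, j=j, n=n,
                        p=phasing_pvalue(j, n, params.i, params.inclusive_tail),
                        n_loci=len({e[0] for e in phased}),
                        strand_counts=dict(strand_counts),
                    )
                )
            w += step
    n_windows = len(windows)
    critical = params.alpha / n_windows if n_windows else params.alpha
    for win in windows:
        failed = []
        if not win.p < critical:
            failed.append("p")
        if not (win.n > 0 and win.j / win.n >= params.min_phased_frac):
            failed.append("phased_frac")
        if win.n_loci < params.min_loci:
            failed.append("min_loci")
        phased_total = sum(win.strand_counts.values())
        if phased_total and max(win.strand_counts.values()) / phased_total > params.max_strand_frac:
            failed.append("strand_bias")
        win.filters_failed = tuple(failed)
        win.passed = not failed

    phasirnas: list[AlignmentRecord] = []
    seen: set[tuple[str, int, str, str]] = set()
    called = [w for w in windows if w.passed]
    for aln in alignments:
        if aln.core_len != params.i:
            continue
        pos = aln.start if aln.strand == "+" else aln.start - 2
        for win in called:
            if (
                win.target == aln.target_id
                and win.start <= pos < win.start + params.window
                and pos % params.i == win.register
            ):
                key = (aln.target_id, aln.start, aln.strand, aln.read_seq)
                if key not in seen:
                    seen.add(key)
                    phasirnas.append(aln)
                break
    return windows, phasirnas


def merge_called_windows(
    windows: Iterable[PhaseWindow],
) -> list[tuple[str, int, int]]:
    """Merge overlapping called windows into maximal (target, start, end)
    runs for reporting."""
    called = sorted(
        ((w.target, w.start, w.end) for w in windows if w.passed),
    )
    merged: list[tuple[str, int, int]] = []
    for target, start, end in called:
        if merged and merged[-1][0] == target and start <= merged[-1][2] + 1:
            prev = merged[-1]
            merged[-1] = (target, prev[1], max(prev[2], end))
        else:
            merged.append((target, start, end))
    return merged
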