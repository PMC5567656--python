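"""piRNA candidate calling and the ping-pong signature.

Reads that survive every other annotation stage are mapped (exact match
by default, both strands) to known piRNA-producing loci; hits become
"piRNA candidates".  Secondary piRNA biogenesis (the ping-pong cycle)
leaves a characteristic bias for opposite-strand read pairs whose 5'
ends overlap by exactly 10 nt; the signature is quantified as a Z-score
of the 10-nt bin against the background bins 1-9 and 11-20.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import AlignmentRecord, ReadSet, ReferenceRecord
from .mapping import MapParams, map_reads

OVERLAP_RANGE = range(1, 21)
SIGNATURE_OVERLAP = 10


@dataclass(frozen=True)
class PingPongProfile:
    overlap_counts: dict[int, float]
    z_score: float | None  # None when the background sd is zero


def call_pirna_candidates(
    reads: ReadSet,
    cluster_refs: Sequence[ReferenceRecord],
    max_mismatch: int = 0,
) -> tuple[ReadSet, ReadSet, list[AlignmentRecord]]:
    """Split residual reads into (piRNA candidates, not annotated).

    Also returns the cluster alignments of the candidate reads for
    downstream length/composition and ping-pong reporting.
    """
    params = MapParams(max_mismatch=max_mismatch, strand_mode="both")
    alignments = map_reads(reads.entries, cluster_refs, params)
    candidate_seqs = {a.read_seq for a in alignments}
    return reads.subset(candidate_seqs), reads.without(candidate_seqs), alignments


def pingpong_histogram(alignments: Iterable[AlignmentRecord]) -> dict[int, float]:
    """Weighted 5'-overlap histogram over d = 1..20.

    For every opposite-strand pair on the same target whose 5' ends
    overlap by d nt, the product of the two read counts is added to bin
    d.  With a plus-strand 5' end at p and a minus-strand 5' end at q
    (both in plus coordinates), the overlap is d = q - p + 1.
    """
    plus5: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    minus5: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for aln in alignments:
        side = plus5 if aln.strand == "+" else minus5
        side[aln.target_id][aln.five_prime] += aln.count
    bins = {d: 0.0 for d in OVERLAP_RANGE}
    for target, minus_ends in minus5.items():
        plus_ends = plus5.get(target)
        if not plus_ends:
            continue
        for q, c_minus in minus_ends.items():
            for d in OVERLAP_RANGE:
                c_plus = plus_ends.get(q - d + 1)
                if c_plus:
                    bins[d] += c_plus * c_minus
    return bins


def pingpong_zscore(overlap_counts: dict[int, float]) -> float | None:
    """Z-score of the 10-nt overlap bin against bins {1..9, 11..20}.

    z = (count[10] - mean(background)) / sd(background) with the sample
    standard deviation; undefined (None) when the background is
    constant.
    """
    background = np.array(
        [overlap_counts.get(d, 0.0) for d in OVERLAP_RANGE if d != SIGNATURE_OVERLAP]
    )
    sd = background.std(ddof=1)
    if sd == 0:
        return None
    return float((overlap_counts.get(SIGNATURE_OVERLAP, 0.0) - background.mean()) / sd)


def pingpong_profile(alignments: Iterable[AlignmentRecord]) -> PingPongProfile:
    bins = pingpong_histogram(alignments)
    return PingPongProfile(overlap_counts=bins, z_score=pingpong_zscore(bins))
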