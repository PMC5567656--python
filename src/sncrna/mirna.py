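"""Tiered miRNA / isomiR annotation with tailing and modification profiling.

Reads are annotated against mature miRNAs placed on their hairpin
precursors in four tiers, in strict order: (i) canonical miRNAs,
(ii) 3'-tailed canonical miRNAs, (iii) offset miRNAs (moRs, 5' end
shifted within a window around the mature 5' end), (iv) 3'-tailed
offset miRNAs.  The four tiers are first run with the reference records
of the library's own species and then repeated with the union of all
other species (cross-species pass), recording the source species per
hit.  A read is assigned to the first tier in which it has at least one
hit; counts of multi-gene hits within the winning tier are apportioned
uniformly per gene.

Defaults: at most 2 non-template 3' nucleotides and at most 1 internal
modification (substitution at a templated position).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import ReadSet, ReferenceRecord
from .mapping import MapParams, find_tailed_occurrences

TIERS = ("canonical", "tailed", "offset", "tailed-offset")
SCOPES = ("self-species", "cross-species")


@dataclass(frozen=True)
class MirnaParams:
    max_tail: int = 2
    max_internal: int = 1
    offset_window: int = 5
    species: str = ""  # self species tag; empty = first species seen

    def __post_init__(self) -> None:
        if self.max_tail < 0 or self.max_internal < 0 or self.offset_window < 0:
            raise ValueError("miRNA parameters must be >= 0")


@dataclass(frozen=True)
class Mature:
    gene: str
    species: str
    hairpin_id: str
    start: int  # 1-based on hairpin
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MirnaRef:
    """Mature miRNAs located on hairpin precursors.

    Built from class-tagged FASTA records: hairpins as
    ``>hairpin|<species>|<id>`` and matures as
    ``>mirna|<species>|<gene>|hairpin=<id>|start=<s>|end=<e>``.
    Every mature must map exactly within its hairpin.
    """

    hairpins: dict[str, ReferenceRecord] = field(default_factory=dict)
    matures: list[Mature] = field(default_factory=list)

    @classmethod
    def from_records(cls, records: Iterable[ReferenceRecord]) -> "MirnaRef":
        ref = cls()
        matures_raw = []
        for rec in records:
            if rec.rna_class == "hairpin":
                species = rec.attrs.get("field1", "")
                hp_id = rec.attrs.get("field2", rec.record_id)
                ref.hairpins[hp_id] = ReferenceRecord(
                    record_id=hp_id, sequence=rec.sequence,
                    rna_class="hairpin", attrs={"species": species},
                )
            elif rec.rna_class == "mirna":
                matures_raw.append(rec)
        for rec in matures_raw:
            species = rec.attrs.get("field1", "")
            gene = rec.attrs.get("field2", rec.record_id)
            hp_id = rec.attrs["hairpin"]
            start, end = int(rec.attrs["start"]), int(rec.attrs["end"])
            hp = ref.hairpins.get(hp_id)
            if hp is None:
                raise ValueError(f"mature {gene}: unknown hairpin {hp_id}")
            if hp.sequence[start - 1: end] != rec.sequence:
                raise ValueError(
                    f"mature {gene} does not match hairpin {hp_id} at {start}..{end}"
                )
            ref.matures.append(Mature(gene, species, hp_id, start, end))
        return ref

    def species_tags(self) -> list[str]:
        seen: list[str] = []
        for m in self.matures:
            if m.species not in seen:
                seen.append(m.species)
        return seen


@dataclass(frozen=True)
class MirnaHit:
    """One read assigned to one miRNA gene in its winning tier."""

    read_seq: str
    gene: str
    species: str
    scope: str  # self-species | cross-species
    tier: str  # canonical | tailed | offset | tailed-offset
    tail: str
    modifications: tuple[tuple[int, str, str], ...]  # (mature pos, from, to)
    offset: int  # read 5' end minus mature 5' end, nt
    count: float  # apportioned read count


def classify_offset(
    read_start: int, mature_start: int, offset_window: int
) -> bool:
    """True iff the read 5' end lies within +-offset_window of the mature
    5' end but is not the canonical start."""
    delta = read_start - mature_start
    return delta != 0 and abs(delta) <= offset_window


def _hits_for_read(
    seq: str, ref: MirnaRef, matures: Sequence[Mature], params: MirnaParams
) -> dict[str, list[tuple[Mature, int, str, tuple[tuple[int, str, str], ...]]]]:
    """Candidate hits per tier for one read.

    Returns tier -> list of (mature, offset, tail, modifications at
    mature coordinates)."""
    map_params = MapParams(
        max_mismatch=params.max_internal, max_tail=params.max_tail,
        strand_mode="plus-only",
    )
    by_hairpin: dict[str, list[Mature]] = defaultdict(list)
    for m in matures:
        by_hairpin[m.hairpin_id].append(m)
    tiers: dict[str, list] = {t: [] for t in TIERS}
    for hp_id, hp_matures in by_hairpin.items():
        hp = ref.hairpins[hp_id]
        for aln in find_tailed_occurrences(seq, hp, map_params):
            for mat in hp_matures:
                delta = aln.start - mat.start
                if delta == 0:
                    tier = "canonical" if not aln.tail else "tailed"
                elif classify_offset(aln.start, mat.start, params.offset_window):
                    tier = "offset" if not aln.tail else "tailed-offset"
                else:
                    continue
                # modifications in mature coordinates (templated positions only)
                mods = tuple(
                    (pos + delta, ref_base, read_base)
                    for pos, read_base, ref_base in aln.mismatches
                )
                tiers[tier].append((mat, delta, aln.tail, mods))
    return tiers


def annotate_mirnas(
    reads: ReadSet, ref: MirnaRef, params: MirnaParams = MirnaParams()
) -> tuple[list[MirnaHit], ReadSet]:
    """Assign reads to miRNA tiers; returns (hits, unassigned reads).

    Each read lands in exactly one (scope, tier) cell or stays
    unassigned; within the winning tier its count is split uniformly
    over the distinct genes hit.
    """
    species_order = ref.species_tags()
    self_species = params.species or (species_order[0] if species_order else "")
    self_matures = [m for m in ref.matures if m.species == self_species]
    cross_matures = [m for m in ref.matures if m.species != self_species]

    hits: list[MirnaHit] = []
    assigned: set[str] = set()
    for seq, count in reads:
        for scope, matures in (
            ("self-species", self_matures), ("cross-species", cross_matures)
        ):
            if not matures:
                continue
            tiers = _hits_for_read(seq, ref, matures, params)
            placed = False
            for tier in TIERS:
                cands = tiers[tier]
                if not cands:
                    continue
                genes = sorted({(mat.gene, mat.species) for mat, _, _, _ in cands})
                share = count / len(genes)
                emitted = set()
                for mat, delta, tail, mods in cands:
                    key = (mat.gene, mat.species)
                    if key in emitted:
                        continue  # one hit per gene in the winning tier
                    emitted.add(key)
                    hits.append(
                        MirnaHit(
                            read_seq=seq, gene=mat.gene, species=mat.species,
                            scope=scope, tier=tier, tail=tail,
                            modifications=mods, offset=delta, count=share,
                        )
                    )
                placed = True
                break
            if placed:
                assigned.add(seq)
                break
    return hits, reads.without(assigned)


def modification_matrix(hits: Iterable[MirnaHit]) -> dict[tuple[int, str], float]:
    """Count-weighted internal-modification matrix.

    Keys are (1-based mature position, "X->Y"); values are apportioned
    read counts.  Positions outside the mature (possible for offset
    reads) are excluded.
    """
    matrix: dict[tuple[int, str], float] = defaultdict(float)
    for hit in hits:
        for pos, from_base, to_base in hit.modifications:
            if pos >= 1:
                matrix[(pos, f"{from_base}->{to_base}")] += hit.count
    return dict(matrix)


def tail_composition(hits: Iterable[MirnaHit]) -> dict[str, float]:
    """Count-weighted 3'-tail composition table.

    Mono- and di-nucleotide tails of a single base are keyed by that
    base ('A', 'AA', ...); mixed di-nucleotide tails are pooled under
    'mixed'.  Untailed hits are ignored.
    """
    table: dict[str, float] = defaultdict(float)
    for hit in hits:
        if not hit.tail:
            continue
        if len(set(hit.tail)) == 1:
            table[hit.tail] += hit.count
        else:
            table["mixed"] += hit.count
    return dict(table)
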