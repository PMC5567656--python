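"""Seeded generators for synthetic references, libraries and map files.

Every fixture the test-suite and the acceptance runs need is generated
here deterministically from an integer seed: random hairpins with
planted mature miRNAs, padded tRNAs with planted oligo-T trailer
signals, piRNA cluster contigs, a random genome with planted phased
loci, and the corresponding labeled read sets.  References are random
sequences with planted features, so everything runs without downloads;
real reference collections in the same FASTA header dialects remain
drop-in compatible.

Truth labels attached to every emitted read are sufficient to compute
confusion matrices for each annotation stage.  For the miRNA grid the
truth tier is derived from what the constructed read *is* relative to
its hairpin template (a dialed-in tail base that happens to match the
template continuation is templated, hence part of the core), not from
the parameter that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .core import AlignmentRecord, ReadSet, ReferenceRecord, revcomp
from .ncrna import TrnaModel, build_trna_model

_BASES = "ACGT"


@dataclass(frozen=True)
class LabeledRead:
    sequence: str
    count: int
    category: str  # miRNA | tRNA | piRNA | low-complexity | background | ...
    gene: str = ""
    tier: str = ""  # miRNA tier or tRF class
    tail: str = ""
    extra: tuple[tuple[str, str], ...] = ()


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = _BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _dedupe(labeled: Iterable[LabeledRead]) -> list[LabeledRead]:
    """Merge duplicate sequences; on a truth conflict keep the first label."""
    by_seq: dict[str, LabeledRead] = {}
    for lr in labeled:
        prev = by_seq.get(lr.sequence)
        if prev is None:
            by_seq[lr.sequence] = lr
        else:
            by_seq[lr.sequence] = LabeledRead(
                sequence=prev.sequence, count=prev.count + lr.count,
                category=prev.category, gene=prev.gene, tier=prev.tier,
                tail=prev.tail, extra=prev.extra,
            )
    return list(by_seq.values())


def to_readset(labeled: Sequence[LabeledRead]) -> ReadSet:
    return ReadSet(tuple((lr.sequence, lr.count) for lr in labeled))


# ---------------------------------------------------------------------------
# miRNA references and test grid
# ---------------------------------------------------------------------------

def gen_hairpin_refs(
    n_hairpins: int,
    seed: int,
    species: str = "syn",
    mature_len: int = 21,
    flank5: int = 8,
    flank3: int = 30,
) -> list[ReferenceRecord]:
    """Random hairpin precursors with one planted mature miRNA each.

    Emits paired records in the reference header dialect:
    ``hairpin|<species>|<id>`` and
    ``mirna|<species>|<gene>|hairpin=<id>|start=<s>|end=<e>``.
    The mature sits ``flank5`` nt into the precursor, leaving room for
    5'-offset reads on both sides.
    """
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_hairpins):
        hp_id = f"{species}-hp-{k + 1}"
        gene = f"{species}-mir-{k + 1}"
        seq = _random_seq(rng, flank5 + mature_len + flank3)
        start, end = flank5 + 1, flank5 + mature_len
        records.append(
            ReferenceRecord(
                record_id=f"hairpin|{species}|{hp_id}", sequence=seq,
                rna_class="hairpin",
                attrs={"field1": species, "field2": hp_id},
            )
        )
        records.append(
            ReferenceRecord(
                record_id=f"mirna|{species}|{gene}|hairpin={hp_id}|start={start}|end={end}",
                sequence=seq[start - 1: end], rna_class="mirna",
                attrs={
                    "field1": species, "field2": gene, "hairpin": hp_id,
                    "start": str(start), "end": str(end),
                },
            )
        )
    return records


def _effective_tail(read: str, hairpin: str, start: int) -> str:
    """Maximal run of 3'-terminal read bases disagreeing with the
    template continuation (the tail the read actually carries)."""
    start0 = start - 1
    tail_len = 0
    for i in range(len(read) - 1, -1, -1):
        pos = start0 + i
        if pos >= len(hairpin) or read[i] != hairpin[pos]:
            tail_len += 1
        else:
            break
    return read[len(read) - tail_len:] if tail_len else ""


def gen_mirna_testset(
    refs: Sequence[ReferenceRecord],
    seed: int,
    offsets: Sequence[int] = tuple(range(-5, 6)),
    tail_lengths: Sequence[int] = (0, 1, 2),
    internal_mm: Sequence[int] = (0, 1),
    gene_count_range: tuple[int, int] | None = None,
) -> list[LabeledRead]:
    """Enumerate the artificial miRNA grid for every mature record.

    For each mature miRNA, every combination of 5' offset, 3' tail
    (all homo-/hetero-polymers of the requested lengths over ACGT) and
    internal mismatch scenario is emitted once.  Reads carry count 1, or
    a per-gene count drawn from ``gene_count_range`` to emulate an
    expression profile.  The truth tier is re-derived from the finished
    read against its hairpin.
    """
    rng = np.random.default_rng(seed)
    hairpins = {
        r.attrs.get("field2", r.record_id): r.sequence
        for r in refs if r.rna_class == "hairpin"
    }
    tails: list[str] = []
    for t in sorted(tail_lengths):
        if t == 0:
            tails.append("")
        else:
            tails.extend("".join(p) for p in product(_BASES, repeat=t))
    out: list[LabeledRead] = []
    for rec in refs:
        if rec.rna_class != "mirna":
            continue
        gene = rec.attrs.get("field2", rec.record_id)
        hp = hairpins[rec.attrs["hairpin"]]
        m_start, m_end = int(rec.attrs["start"]), int(rec.attrs["end"])
        gene_count = (
            int(rng.integers(gene_count_range[0], gene_count_range[1] + 1))
            if gene_count_range is not None
            else 1
        )
        for offset, tail, n_mm in product(offsets, tails, internal_mm):
            core_start = m_start + offset
            if core_start < 1 or m_end > len(hp):
                continue
            core = hp[core_start - 1: m_end]
            if n_mm:
                # one substitution away from both termini so the planted
                # tail run and the 5' anchor stay intact
                if len(core) < 8:
                    continue
                pos = int(rng.integers(3, len(core) - 3))
                alts = [b for b in _BASES if b != core[pos]]
                base = alts[int(rng.integers(0, len(alts)))]
                core = core[:pos] + base + core[pos + 1:]
            read = core + tail
            eff_tail = _effective_tail(read, hp, core_start)
            if len(eff_tail) > 2:
                continue  # degenerate cell: effective tail exceeds the tail budget
            # core mismatches under the tail convention: the injected
            # substitution plus any dialed tail base that is stranded in
            # the core because a later tail base matches the template
            eff_core = read[: len(read) - len(eff_tail)]
            template = hp[core_start - 1: core_start - 1 + len(eff_core)]
            if sum(a != b for a, b in zip(eff_core, template)) > 1:
                continue  # degenerate cell: tail/template coincidence adds a 2nd mismatch
            tier = (
                ("canonical" if not eff_tail else "tailed")
                if offset == 0
                else ("offset" if not eff_tail else "tailed-offset")
            )
            out.append(
                LabeledRead(
                    sequence=read, count=gene_count, category="miRNA", gene=gene,
                    tier=tier, tail=eff_tail,
                )
            )
    return _dedupe(out)


# ---------------------------------------------------------------------------
# tRNA references and tRF test set
# ---------------------------------------------------------------------------

def gen_trna_refs(
    n_trnas: int,
    seed: int,
    mature_lengths: Sequence[int] = (76, 72),
    pad5: int = 20,
    pad3: int = 30,
    oligo_t_at: int = 15,
) -> list[ReferenceRecord]:
    """Random padded tRNA references (``trna|<id>|pad5=..|pad3=..``).

    The 3' trailer is drawn from {A,C,G} with a single oligo-T signal
    (TTTT) planted at trailer position ``oligo_t_at``, and starts with a
    non-C base so an appended CCA is recognizably untemplated.
    """
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_trnas):
        L = mature_lengths[k % len(mature_lengths)]
        mature = _random_seq(rng, L)
        leader = _random_seq(rng, pad5)
        trailer = list(_random_seq(rng, pad3, alphabet="ACG"))
        trailer[0] = "A" if trailer[0] == "C" else trailer[0]
        trailer[oligo_t_at - 1: oligo_t_at + 3] = list("TTTT")
        trna_id = f"syn-trna-{k + 1}"
        records.append(
            ReferenceRecord(
                record_id=f"trna|{trna_id}|pad5={pad5}|pad3={pad3}",
                sequence=leader + mature + "".join(trailer),
                rna_class="trna",
                attrs={"field1": trna_id, "pad5": str(pad5), "pad3": str(pad3)},
            )
        )
    return records


def _trf_read_coords(model: TrnaModel) -> list[tuple[str, int, int, str]]:
    """(class, mature-relative start, end, appended suffix) per tRF class."""
    L = model.mature_len
    mid_ac = (model.ac_start + model.ac_end) // 2
    coords = [
        ("5' tRF", 1, model.d_loop_end, ""),
        ("5' tR-half", 1, mid_ac, ""),
        ("3' tRF", model.tpsi_start, L, ""),
        ("3' CCA-tRF", model.tpsi_start + 1, L, "CCA"),
        ("3' tR-half", mid_ac, L, ""),
        ("tRNA-leader", -14, 0, ""),
        ("misc-tRF", 12, 45, ""),
    ]
    if model.oligo_t is not None:
        coords.append(("tRF-1", L + 1, L + model.oligo_t - 1, ""))
    return coords


def gen_trf_testset(
    trna_records: Sequence[ReferenceRecord],
    seed: int,
    mismatch_fraction: float = 0.5,
) -> list[LabeledRead]:
    """One read per tRF class per tRNA, with one internal substitution in
    ``mismatch_fraction`` of the emitted sequences."""
    rng = np.random.default_rng(seed)
    out: list[LabeledRead] = []
    emitted = 0
    for rec in trna_records:
        model = build_trna_model(rec)
        for cls, s, e, suffix in _trf_read_coords(model):
            start0 = model.pad5 + s - 1
            end0 = model.pad5 + e
            read = model.sequence[start0:end0]
            if len(read) < 10:
                continue
            # deterministic schedule hitting exactly the requested fraction
            if int((emitted + 1) * mismatch_fraction) > int(emitted * mismatch_fraction):
                pos = int(rng.integers(3, len(read) - 3))
                alts = [b for b in _BASES if b != read[pos]]
                read = read[:pos] + alts[int(rng.integers(0, 3))] + read[pos + 1:]
            read += suffix
            out.append(
                LabeledRead(
                    sequence=read, count=1, category="tRNA",
                    gene=model.trna_id, tier=cls,
                )
            )
            emitted += 1
    return _dedupe(out)


# ---------------------------------------------------------------------------
# phased loci and map files
# ---------------------------------------------------------------------------

@dataclass
class PhasedTruth:
    genome: str
    target: str
    loci: list[tuple[int, int]] = field(default_factory=list)  # (start, end)
    phased_keys: set[tuple[int, str]] = field(default_factory=set)  # (start, strand)


def gen_phased_testset(
    n_loci: int,
    seed: int,
    i: int = 21,
    reads_per_pos: int = 1,
    background_reads: int = 0,
    positions_per_locus: int = 20,
    genome_len: int = 100_000,
    target: str = "chrS",
    background_avoids_loci: bool = True,
) -> tuple[list[AlignmentRecord], PhasedTruth]:
    """Planted phased loci plus uniform background on a random genome.

    Each locus occupies ``positions_per_locus`` consecutive phase
    registers of length ``i``; strands alternate so perfect duplexes
    (minus reads shifted by the 2-nt 3' overhang) share the register.
    Background reads of length ``i`` are placed uniformly at random on
    both strands; with ``background_avoids_loci`` (the default) they are
    kept at least one kilobase away from every planted locus, emulating
    non-phased sequences that map elsewhere in the genome.
    """
    rng = np.random.default_rng(seed)
    genome = _random_seq(rng, genome_len)
    truth = PhasedTruth(genome=genome, target=target)
    alignments: list[AlignmentRecord] = []
    locus_span = positions_per_locus * i
    spacing = genome_len // max(n_loci, 1)
    for k in range(n_loci):
        base = k * spacing + int(rng.integers(100, max(101, spacing - locus_span - 200)))
        truth.loci.append((base, base + locus_span - 1))
        for j in range(positions_per_locus):
            c = base + j * i  # consolidated register position
            if j % 2 == 0:
                start, strand = c, "+"
                seq = genome[start - 1: start - 1 + i]
            else:
                start, strand = c + 2, "-"
                seq = revcomp(genome[start - 1: start - 1 + i])
            alignments.append(
                AlignmentRecord(
                    read_seq=seq, target_id=target, start=start,
                    strand=strand, count=reads_per_pos,
                )
            )
            truth.phased_keys.add((start, strand))
    margin = 1000
    for _ in range(background_reads):
        while True:
            start = int(rng.integers(1, genome_len - i))
            if not background_avoids_loci or all(
                start < s - margin or start > e + margin for s, e in truth.loci
            ):
                break
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome[start - 1: start - 1 + i]
        if strand == "-":
            seq = revcomp(seq)
        alignments.append(
            AlignmentRecord(
                read_seq=seq, target_id=target, start=start,
                strand=strand, count=1,
            )
        )
    return alignments, truth


# ---------------------------------------------------------------------------
# adapter-ligated raw reads
# ---------------------------------------------------------------------------

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# (window length, substitutions tolerated) pairs that dominate the
# trimmer's search space: exact 6-mers cover exact 7/8-mers, 1-mismatch
# 9-mers cover 10/11-mers, 2-mismatch 12-mers stand alone
_SCREEN_LADDER = ((6, 0), (9, 1), (12, 2))


def _boundary_identifiable(read: str, insert_len: int, adapter: str) -> bool:
    """True iff no adapter-derived motif near-matches the read upstream
    of the true insert/adapter boundary.

    An insert that spuriously contains (or runs into) an adapter window
    within the trimmer's mismatch ladder makes its own boundary
    ill-defined: no adapter remover could recover it.  Such reads are
    rejected at generation so the truth stays well-posed.
    """
    for L, allowance in _SCREEN_LADDER:
        for p in range(insert_len):
            if p + L > len(read):
                break
            window = read[p: p + L]
            for j in range(len(adapter) - L + 1):
                mm = sum(a != b for a, b in zip(window, adapter[j: j + L]))
                if mm <= allowance:
                    return False
    return True


def gen_adapter_testset(
    n_reads: int,
    seed: int,
    adapter: str = DEFAULT_ADAPTER,
    read_len: int = 36,
    insert_len_range: tuple[int, int] = (24, 28),
    stub: int | None = None,
) -> tuple[ReadSet, dict[str, str]]:
    """Error-free adapter-ligated raw reads with known inserts.

    Each read is ``(insert + adapter)[:read_len]``; insert lengths are
    miRNA-scale by default (24-28 nt on 36-nt reads), so reads carry the
    full 12-nt adapter motif down to its 7-nt truncation.  With ``stub``
    set, every insert has length ``read_len - stub`` so only the first
    ``stub`` adapter bases are sequenced (the positional-bias trimming
    scenario when ``stub`` is below the minimal motif length).  Inserts
    are screened with :func:`_boundary_identifiable`.
    Returns (raw reads, raw read -> insert truth map).
    """
    rng = np.random.default_rng(seed)
    lo, hi = insert_len_range
    truth: dict[str, str] = {}
    pairs = []
    for _ in range(n_reads):
        ins_len = read_len - stub if stub is not None else int(rng.integers(lo, hi + 1))
        for _attempt in range(100):
            insert = _random_seq(rng, ins_len)
            read = (insert + adapter + _random_seq(rng, read_len))[:read_len]
            if _boundary_identifiable(read, ins_len, adapter):
                break
        else:  # pragma: no cover - would need a pathological adapter
            raise RuntimeError("could not draw an identifiable insert")
        if read in truth and truth[read] != insert:
            continue  # astronomically rare collision with conflicting truth
        truth[read] = insert
        pairs.append((read, 1))
    return ReadSet.from_iter(pairs), truth


# ---------------------------------------------------------------------------
# piRNA clusters and ping-pong pairs
# ---------------------------------------------------------------------------

def gen_pirna_cluster(seed: int, length: int = 10_000, cluster_id: str = "syn-pic-1") -> ReferenceRecord:
    rng = np.random.default_rng(seed)
    return ReferenceRecord(
        record_id=f"picluster|{cluster_id}", sequence=_random_seq(rng, length),
        rna_class="picluster", attrs={"field1": cluster_id},
    )


def gen_pirna_testset(
    cluster: ReferenceRecord,
    n_reads: int,
    seed: int,
    u5_fraction: float = 0.85,
    length_range: tuple[int, int] = (26, 30),
) -> list[LabeledRead]:
    """piRNA candidate reads drawn from a cluster contig with a tunable
    5'-U fraction (substrings whose first base matches the requested
    composition are sampled)."""
    rng = np.random.default_rng(seed)
    seq = cluster.sequence
    out = []
    for _ in range(n_reads):
        want_u = rng.random() < u5_fraction  # decided before sampling
        while True:
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            start = int(rng.integers(0, len(seq) - L))
            read = seq[start: start + L]
            if (read[0] == "T") == want_u:
                break
        out.append(LabeledRead(sequence=read, count=1, category="piRNA"))
    return _dedupe(out)


def gen_pingpong_testset(
    n_pairs: int,
    seed: int,
    offset_d: int | None = 10,
    read_len: int = 28,
    target_len: int = 50_000,
    target: str = "pic1",
) -> list[AlignmentRecord]:
    """Opposite-strand read pairs with 5' overlap ``offset_d``.

    With ``offset_d=None`` the minus reads are placed uniformly at
    random instead (null model without any overlap structure).
    """
    rng = np.random.default_rng(seed)
    contig = _random_seq(rng, target_len)
    out = []
    for _ in range(n_pairs):
        p = int(rng.integers(read_len + 25, target_len - read_len - 25))
        c_plus = int(rng.integers(1, 4))
        c_minus = int(rng.integers(1, 4))
        out.append(
            AlignmentRecord(
                read_seq=contig[p - 1: p - 1 + read_len], target_id=target,
                start=p, strand="+", count=c_plus,
            )
        )
        if offset_d is None:
            q5 = int(rng.integers(read_len, target_len - 1))
        else:
            q5 = p + offset_d - 1  # minus-strand 5' end in plus coordinates
        m_start = q5 - read_len + 1
        out.append(
            AlignmentRecord(
                read_seq=revcomp(contig[m_start - 1: m_start - 1 + read_len]),
                target_id=target, start=m_start, strand="-", count=c_minus,
            )
        )
    return out


# ---------------------------------------------------------------------------
# miscellaneous library components
# ---------------------------------------------------------------------------

def gen_ncrna_refs(
    seed: int,
    classes: Sequence[str] = ("rRNA", "snRNA", "snoRNA", "lncRNA"),
    per_class: int = 3,
    length: int = 300,
) -> list[ReferenceRecord]:
    rng = np.random.default_rng(seed)
    records = []
    for cls in classes:
        for k in range(per_class):
            rec_id = f"ncrna|{cls}|syn-{cls}-{k + 1}"
            records.append(
                ReferenceRecord(
                    record_id=rec_id, sequence=_random_seq(rng, length),
                    rna_class="ncrna", attrs={"field1": cls, "field2": f"syn-{cls}-{k + 1}"},
                )
            )
    return records


def gen_low_complexity_reads(n_reads: int, seed: int) -> list[LabeledRead]:
    """Reads built from 1-3 nt motif repeats (rejected by the filter)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reads):
        m = int(rng.integers(1, 4))
        motif = _random_seq(rng, m)
        L = int(rng.integers(20, 31))
        out.append(
            LabeledRead(
                sequence=(motif * (L // m + 1))[:L], count=1,
                category="low-complexity",
            )
        )
    return _dedupe(out)


def gen_background_reads(n_reads: int, seed: int, length_range=(20, 30)) -> list[LabeledRead]:
    """Random reads matching no synthetic reference (stay unannotated)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reads):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append(LabeledRead(sequence=_random_seq(rng, L), count=1, category="background"))
    return _dedupe(out)
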