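"""Reading and writing of external formats.

Sequence input is FASTA, FASTQ or collapsed FASTA (read counts encoded
in headers as ``>name-COUNT`` or ``>name COUNT``).  Map files are SAM or
the 6-column ELAND3 dialect::

    target <TAB> 1-based position <TAB> sequence (read orientation)
           <TAB> read count <TAB> strand (+/-) <TAB> mismatch count

SAM and ELAND3 coordinates are 1-based leftmost on the target plus
strand; minus-strand SAM sequences are restored to read orientation.
Only ungapped SAM alignments (pure-match CIGAR) are consumed; gapped
records are skipped with a warning.  All result tables are written as
tab-separated UTF-8 with a header line starting ``#``.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

from .core import AlignmentRecord, ReadSet, ReferenceRecord, normalize_sequence, revcomp

_COLLAPSED_DASH = re.compile(r"^(?P<name>.*)-(?P<count>\d+)$")
_COLLAPSED_SPACE = re.compile(r"^(?P<name>\S.*)\s+(?P<count>\d+)$")
_PURE_MATCH_CIGAR = re.compile(r"^(\d+)(M|=|X)$|^\*$")


class MapFileError(ValueError):
    """Raised for malformed or unsupported map-file content."""


def _collapsed_count(header: str) -> int:
    """Extract the read count from a collapsed-FASTA header.

    Accepts the ``name-COUNT`` and ``name COUNT`` dialects; an ambiguous
    header falls back to count 1 with a warning.
    """
    for pattern in (_COLLAPSED_SPACE, _COLLAPSED_DASH):
        m = pattern.match(header.strip())
        if m:
            count = int(m.group("count"))
            if count <= 0:
                raise ValueError(f"non-positive read count in header {header!r}")
            return count
    warnings.warn(f"no read count found in collapsed header {header!r}; using 1")
    return 1


def read_sequences(path: str | Path, format: str = "fasta") -> ReadSet:
    """Read a small-RNA library and collapse it into a :class:`ReadSet`.

    ``format`` is one of ``fasta``, ``fastq`` or ``collapsed-fasta``.
    Plain FASTA/FASTQ records count 1 each; collapsed FASTA takes counts
    from the header dialect.  Sequences are upper-cased and U converted
    to T; identical sequences are merged with summed counts.
    """
    path = Path(path)
    if format in ("fasta", "fastq"):
        records = SeqIO.parse(str(path), format)
        pairs = ((str(rec.seq), 1) for rec in records)
        return ReadSet.from_iter(pairs)
    if format == "collapsed-fasta":
        pairs = []
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.description or rec.id
            pairs.append((str(rec.seq), _collapsed_count(header)))
        return ReadSet.from_iter(pairs)
    raise ValueError(f"unknown sequence format {format!r}")


def _read_name_count(name: str) -> int:
    """Read count encoded in a collapsed read name, else 1."""
    m = _COLLAPSED_DASH.match(name)
    return int(m.group("count")) if m else 1


def _record_from_sam_fields(
    qname: str, flag: int, rname: str, pos: int, cigar: str, seq: str, line_no: int
) -> AlignmentRecord | None:
    if flag & 4 or rname in ("*", ""):
        return None  # unmapped
    if not _PURE_MATCH_CIGAR.match(cigar):
        warnings.warn(f"skipping gapped/clipped SAM record {qname!r} (CIGAR {cigar})")
        return None
    if pos < 1:
        raise MapFileError(f"SAM line {line_no}: coordinate {pos} < 1")
    seq = normalize_sequence(seq)
    strand = "-" if flag & 16 else "+"
    if strand == "-":
        seq = revcomp(seq)  # restore read orientation
    return AlignmentRecord(
        read_seq=seq,
        target_id=rname,
        start=pos,
        strand=strand,
        count=_read_name_count(qname),
    )


def _parse_sam(path: Path) -> list[AlignmentRecord]:
    with open(path) as fh:
        first = fh.readline()
    records: list[AlignmentRecord] = []
    if first.startswith("@"):
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for i, aln in enumerate(sam, start=1):
                rec = _record_from_sam_fields(
                    aln.query_name or "",
                    aln.flag,
                    aln.reference_name or "*" if not aln.is_unmapped else "*",
                    (aln.reference_start or 0) + 1,
                    aln.cigarstring or "*",
                    aln.query_sequence or "",
                    i,
                )
                if rec is not None:
                    records.append(rec)
        return records
    # headerless SAM: pysam cannot iterate it, parse the 11 mandatory
    # columns directly
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise MapFileError(f"SAM line {i}: expected >=11 fields, got {len(fields)}")
            try:
                flag, pos = int(fields[1]), int(fields[3])
            except ValueError as exc:
                raise MapFileError(f"SAM line {i}: {exc}") from exc
            rec = _record_from_sam_fields(
                fields[0], flag, fields[2], pos, fields[5], fields[9], i
            )
            if rec is not None:
                records.append(rec)
    return records


def _parse_eland3(path: Path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise MapFileError(f"ELAND3 line {i}: expected 6 fields, got {len(fields)}")
            target, pos_s, seq, count_s, strand, _n_mm = fields
            try:
                pos, count = int(pos_s), int(count_s)
            except ValueError as exc:
                raise MapFileError(f"ELAND3 line {i}: {exc}") from exc
            if pos < 1:
                raise MapFileError(f"ELAND3 line {i}: coordinate {pos} < 1")
            if strand not in ("+", "-"):
                raise MapFileError(f"ELAND3 line {i}: bad strand {strand!r}")
            records.append(
                AlignmentRecord(
                    read_seq=normalize_sequence(seq),
                    target_id=target,
                    start=pos,
                    strand=strand,
                    count=count,
                )
            )
    return records


def parse_map_file(path: str | Path, dialect: str = "sam") -> list[AlignmentRecord]:
    """Parse a SAM or ELAND3 map file into alignment records.

    Unmapped records are dropped; minus-strand SAM sequences are
    reverse-complemented back to read orientation.  Per-record read
    counts come from the collapsed read-name dialect (``name-COUNT``),
    else 1.
    """
    path = Path(path)
    if dialect == "sam":
        return _parse_sam(path)
    if dialect == "eland3":
        return _parse_eland3(path)
    raise ValueError(f"unknown map-file dialect {dialect!r}")


def write_eland3(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.target_id}\t{rec.start}\t{rec.read_seq}\t{rec.count}\t"
                f"{rec.strand}\t{len(rec.mismatches)}\n"
            )


def write_sam(
    records: Sequence[AlignmentRecord],
    path: str | Path,
    reference_lengths: dict[str, int] | None = None,
) -> None:
    """Write ungapped alignments as SAM with an @SQ header.

    Reference lengths default to the largest coordinate seen per target
    (sufficient for round-tripping through :func:`parse_map_file`).
    """
    if reference_lengths is None:
        reference_lengths = {}
        for rec in records:
            end = rec.start + rec.core_len - 1
            reference_lengths[rec.target_id] = max(
                reference_lengths.get(rec.target_id, 0), end
            )
    names = sorted(reference_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": reference_lengths[n]} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for idx, rec in enumerate(records):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"seq{idx}-{rec.count}"
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = tid[rec.target_id]
            a.reference_start = rec.start - 1
            a.mapping_quality = 255
            seq = rec.core_seq if rec.strand == "+" else revcomp(rec.core_seq)
            a.query_sequence = seq
            a.cigarstring = f"{len(seq)}M"
            out.write(a)


# ---------------------------------------------------------------------------
# reference FASTA collections
# ---------------------------------------------------------------------------

def load_reference_fasta(path: str | Path) -> list[ReferenceRecord]:
    """Load a class-tagged reference FASTA.

    Header fields are ``|``-separated; the first field names the record
    kind (``mirna``, ``hairpin``, ``ncrna``, ``trna``, ``picluster``),
    ``key=value`` fields become attributes, bare fields are kept
    positionally under ``field1``, ``field2``, ...
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        parts = header.split("|")
        kind = parts[0]
        attrs: dict[str, str] = {}
        positional = []
        for part in parts[1:]:
            if "=" in part:
                key, _, value = part.partition("=")
                attrs[key] = value
            else:
                positional.append(part)
        for i, value in enumerate(positional, start=1):
            attrs[f"field{i}"] = value
        out.append(
            ReferenceRecord(
                record_id=header,
                sequence=normalize_sequence(str(rec.seq)),
                rna_class=kind,
                attrs=attrs,
            )
        )
    return out


def write_reference_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.record_id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table(
    path: str | Path, columns: Sequence[str], rows: Iterable[Sequence[object]]
) -> None:
    """Write one tab-separated result table with a '#'-prefixed header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_outputs(tables: dict[str, tuple[Sequence[str], list[Sequence[object]]]],
                  outdir: str | Path) -> list[Path]:
    """Write named result tables deterministically (sorted table names).

    ``tables`` maps a table name to (column names, rows); each table is
    written to ``<outdir>/<name>.tsv``.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        columns, rows = tables[name]
        path = outdir / f"{name}.tsv"
        write_table(path, columns, rows)
        written.append(path)
    return written
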