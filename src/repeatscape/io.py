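"""Readers and writers for the formats the pipeline touches.

FASTA goes through Bio.SeqIO; PAF, 12-column tabular hits, TRF ``.dat`` and
the aligned-pair TSV are parsed directly (one record per data line, never
silently dropped). Coordinate conventions: everything in memory is 0-based
half-open; TRF and tabular hits are 1-based inclusive on disk and converted
here, at the format boundary.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from ._util import FormatError, log
from .records import (
    AlignedPair,
    GenomicInterval,
    PafRecord,
    SequenceRecord,
    TabularHit,
    TandemArray,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_paf",
    "write_paf",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_trf_dat",
    "read_aligned_pairs",
    "write_aligned_pairs",
    "read_bed",
    "write_bed",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file, preserving residue case (soft-mask state).

    Raises FormatError on an empty file, a malformed header, or a duplicated
    record id.
    """
    try:
        bio = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # malformed content
        raise FormatError(f"{path}: {exc}") from exc
    if not bio:
        raise FormatError(f"{path}: no FASTA records found (line 1)")
    records = []
    seen: set[str] = set()
    for r in bio:
        if not r.id:
            raise FormatError(f"{path}: record with empty id")
        if r.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {r.id!r}")
        seen.add(r.id)
        records.append(SequenceRecord(id=r.id, residues=str(r.seq)))
    log.debug("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 60) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ------------------------------------------------------------------ PAF

def _parse_paf_line(line: str, lineno: int, path) -> PafRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 12:
        raise FormatError(
            f"{path}:{lineno}: PAF line has {len(parts)} columns (< 12)"
        )
    is_primary = True
    for tag in parts[12:]:
        if tag.startswith("tp:A:"):
            is_primary = tag[5:] == "P"
    try:
        return PafRecord(
            query_id=parts[0],
            query_length=int(parts[1]),
            query_start=int(parts[2]),
            query_end=int(parts[3]),
            strand=parts[4],
            target_id=parts[5],
            target_length=int(parts[6]),
            target_start=int(parts[7]),
            target_end=int(parts[8]),
            residue_matches=int(parts[9]),
            block_length=int(parts[10]),
            mapping_quality=int(parts[11]),
            is_primary=is_primary,
        )
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def read_paf(path: str | os.PathLike) -> list[PafRecord]:
    """Read a PAF mapping file; optional tags (tp:A:P/S) set primary status."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            records.append(_parse_paf_line(line, lineno, path))
    log.debug("read_paf: %d records from %s", len(records), path)
    return records


def write_paf(records: Iterable[PafRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            tag = "tp:A:P" if r.is_primary else "tp:A:S"
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.query_length, r.query_start, r.query_end,
                        r.strand, r.target_id, r.target_length, r.target_start,
                        r.target_end, r.residue_matches, r.block_length,
                        r.mapping_quality, tag,
                    )
                )
                + "\n"
            )


# -------------------------------------------------------- tabular hits

def read_tabular_hits(path: str | os.PathLike) -> list[TabularHit]:
    """Read 12-column tabular similarity hits (coordinates stay 1-based)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                hits.append(
                    TabularHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        query_start=int(parts[6]),
                        query_end=int(parts[7]),
                        subject_start=int(parts[8]),
                        subject_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    log.debug("read_tabular_hits: %d hits from %s", len(hits), path)
    return hits


def write_tabular_hits(hits: Iterable[TabularHit],
                       path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, h.percent_identity,
                        h.alignment_length, h.mismatches, h.gap_opens,
                        h.query_start, h.query_end, h.subject_start,
                        h.subject_end, h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


# --------------------------------------------------------------- TRF .dat

def read_trf_dat(path: str | os.PathLike) -> list[TandemArray]:
    """Parse a Tandem Repeats Finder ``.dat`` file into TandemArray records.

    Array lines carry (1-based inclusive) start/end, period size, copy
    number, consensus size, percent matches, ... and the consensus sequence;
    coordinates are converted to 0-based half-open here.
    """
    arrays: list[TandemArray] = []
    seq_id: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                seq_id = line.split(None, 1)[1].split()[0]
                continue
            # skip the standard .dat preamble lines
            if line.split()[0] in {"Tandem", "Program", "Gary", "Boston",
                                   "Version", "Parameters:"}:
                continue
            fields = line.split()
            if len(fields) < 14 or not fields[0].isdigit():
                continue
            if seq_id is None:
                raise FormatError(
                    f"{path}:{lineno}: array line before any 'Sequence:' header"
                )
            start_1, end_1 = int(fields[0]), int(fields[1])
            period = int(fields[2])
            copies = float(fields[3])
            percent_matches = float(fields[5])
            consensus = fields[13]
            arrays.append(
                TandemArray(
                    location=GenomicInterval(seq_id, start_1 - 1, end_1),
                    period=period,
                    copy_number=copies,
                    monomer_consensus=consensus,
                    mean_monomer_identity=percent_matches / 100.0,
                )
            )
    log.debug("read_trf_dat: %d arrays from %s", len(arrays), path)
    return arrays


# ----------------------------------------------------- aligned-pair TSV

_PAIR_COLS = ("seq_id", "start", "end", "strand", "family", "superfamily",
              "subgenome", "copy_row", "consensus_row")


def read_aligned_pairs(path: str | os.PathLike) -> list[AlignedPair]:
    """Read the tab-separated copy-vs-consensus alignment dialect.

    Columns: seq_id, start, end, strand, family, superfamily, subgenome,
    copy_row, consensus_row. A header line repeating the column names is
    permitted and skipped.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "seq_id":
                continue
            if len(parts) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 columns, got {len(parts)}"
                )
            try:
                pairs.append(
                    AlignedPair(
                        copy_row=parts[7],
                        consensus_row=parts[8],
                        family=parts[4],
                        superfamily=parts[5],
                        location=GenomicInterval(
                            parts[0], int(parts[1]), int(parts[2]),
                            strand=parts[3],
                        ),
                        subgenome=parts[6],
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    log.debug("read_aligned_pairs: %d pairs from %s", len(pairs), path)
    return pairs


def write_aligned_pairs(pairs: Iterable[AlignedPair],
                        path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PAIR_COLS) + "\n")
        for p in pairs:
            fh.write(
                "\t".join(
                    (
                        p.location.seq_id, str(p.location.start),
                        str(p.location.end), p.location.strand, p.family,
                        p.superfamily, p.subgenome, p.copy_row,
                        p.consensus_row,
                    )
                )
                + "\n"
            )


# ------------------------------------------------------------------ BED

def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 into GenomicInterval records."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                out.append(
                    GenomicInterval(
                        seq_id=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        name=parts[3] if len(parts) > 3 else "",
                        score=float(parts[4]) if len(parts) > 4
                        and parts[4] != "." else 0.0,
                        strand=parts[5] if len(parts) > 5 else ".",
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval],
              path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{iv.score:g}\t{iv.strand}\n"
            )
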