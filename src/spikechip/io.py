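"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA and FASTQ go through Biopython; BED and TSV files are simple enough
to parse directly with line-number error reporting.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

EXPERIMENTAL = "experimental"
SPIKE = "spike"

FastqRead = tuple[str, str, str]  # (id, sequence, quality)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: uppercase sequence} map."""
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        chroms[rec.id] = str(rec.seq).upper()
    if not chroms:
        raise FormatError(f"no FASTA records in {path}")
    return chroms


def write_fasta(chroms: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in chroms.items()]
    SeqIO.write(records, str(path), "fasta")


def iter_fastq(path: str | os.PathLike) -> Iterator[FastqRead]:
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def write_fastq(reads: Iterable[FastqRead], path: str | os.PathLike) -> int:
    n = 0
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_bed6(path: str | os.PathLike) -> list[tuple[str, int, int, str, str, str]]:
    """Read BED6 rows as (chrom, start, end, name, score, strand)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"expected >= 6 BED columns, got {len(parts)}", line=ln)
            chrom, start, end, name, score, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"non-integer BED coordinate: {exc}", line=ln) from exc
            if strand not in "+-":
                raise FormatError(f"bad strand {strand!r}", line=ln)
            if s < 0 or e < s:
                raise FormatError(f"bad interval [{s}, {e})", line=ln)
            rows.append((chrom, s, e, name, score, strand))
    return rows


def write_bed6(rows: Iterable[tuple[str, int, int, str, str, str]],
               path: str | os.PathLike) -> int:
    n = 0
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
            n += 1
    return n


def read_barcode_tsv(path: str | os.PathLike) -> dict[str, str]:
    """Read a sample<TAB>barcode table."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError("expected sample<TAB>barcode", line=ln)
            name, barcode = parts
            if name in entries:
                raise FormatError(f"duplicate sample name {name!r}", line=ln)
            entries[name] = barcode.upper()
    return entries
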