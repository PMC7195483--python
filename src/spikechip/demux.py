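"""In-line barcode demultiplexing with one-mismatch tolerance.

A read is assigned to the sample whose barcode is nearest (in Hamming
distance) to the read's leading bases, provided that distance does not
exceed ``max_mismatch`` and the nearest barcode is unique; ties at the
minimal distance are discarded to the unassigned stream, untrimmed.
N bases count as mismatches.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from . import io as sio
from .errors import ConfigError, MalformedReadError
from .io import FastqRead

UNASSIGNED = "unassigned"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeSpec:
    """Sample-name -> barcode table.

    Pairwise Hamming distance >= ``min_pairwise_distance`` (default 3) is
    enforced so that one-mismatch assignment can never be ambiguous; relax
    it only to study degenerate designs.
    """

    entries: dict[str, str]
    min_pairwise_distance: int = field(default=3, compare=False)

    def __post_init__(self):
        if not self.entries:
            raise ConfigError("barcode table is empty")
        barcodes = list(self.entries.values())
        lengths = {len(b) for b in barcodes}
        if len(lengths) != 1 or 0 in lengths:
            raise ConfigError("barcodes must be non-empty and of equal length")
        for name, bc in self.entries.items():
            if set(bc) - set("ACGT"):
                raise ConfigError(f"barcode for {name!r} is not over {{A,C,G,T}}")
        if len(set(barcodes)) != len(barcodes):
            raise ConfigError("duplicate barcodes")
        for (n1, b1), (n2, b2) in itertools.combinations(self.entries.items(), 2):
            d = hamming(b1, b2)
            if d < self.min_pairwise_distance:
                raise ConfigError(
                    f"barcodes {n1!r}/{n2!r} at Hamming distance {d} < "
                    f"{self.min_pairwise_distance}")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values())))

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, **kwargs) -> "BarcodeSpec":
        return cls(sio.read_barcode_tsv(path), **kwargs)


def _neighbourhood(barcode: str, max_mismatch: int) -> Iterator[tuple[str, int]]:
    """All strings within ``max_mismatch`` of ``barcode`` (ACGTN alphabet)."""
    alphabet = "ACGTN"
    for d in range(max_mismatch + 1):
        for positions in itertools.combinations(range(len(barcode)), d):
            pools = [[c for c in alphabet if c != barcode[i]] for i in positions]
            for subst in itertools.product(*pools):
                variant = list(barcode)
                for i, c in zip(positions, subst):
                    variant[i] = c
                yield "".join(variant), d


class _Classifier:
    """Maps a read prefix to a sample name (or None for unassigned)."""

    def __init__(self, spec: BarcodeSpec, max_mismatch: int):
        if max_mismatch < 0:
            raise ConfigError("max_mismatch must be >= 0")
        self.spec = spec
        self.max_mismatch = max_mismatch
        self.blen = spec.barcode_length
        self.table: dict[str, tuple[str | None, int]] | None = None
        # precompute the mismatch neighbourhood when it is small
        if max_mismatch <= 2 and self.blen <= 16:
            table: dict[str, tuple[str | None, int]] = {}
            for name, bc in spec.entries.items():
                for variant, d in _neighbourhood(bc, max_mismatch):
                    prev = table.get(variant)
                    if prev is None or d < prev[1]:
                        table[variant] = (name, d)
                    elif d == prev[1] and prev[0] != name:
                        table[variant] = (None, d)  # ambiguous at minimal distance
            self.table = table

    def __call__(self, prefix: str) -> str | None:
        if self.table is not None:
            hit = self.table.get(prefix)
            return None if hit is None else hit[0]
        best_name, best_d, tie = None, self.max_mismatch + 1, False
        for name, bc in self.spec.entries.items():
            d = hamming(prefix, bc)
            if d < best_d:
                best_name, best_d, tie = name, d, False
            elif d == best_d:
                tie = True
        return None if tie else best_name


def _classified(reads: Iterable[FastqRead], classifier: _Classifier
                ) -> Iterator[tuple[str | None, FastqRead]]:
    blen = classifier.blen
    for rid, seq, qual in reads:
        if len(seq) <= blen:
            raise MalformedReadError(
                f"read {rid!r} (length {len(seq)}) is not longer than the "
                f"barcode (length {blen})")
        name = classifier(seq[:blen])
        if name is None:
            yield None, (rid, seq, qual)
        else:
            yield name, (rid, seq[blen:], qual[blen:])


def demultiplex(reads: Iterable[FastqRead], spec: BarcodeSpec,
                max_mismatch: int = 1
                ) -> tuple[dict[str, list[FastqRead]], list[FastqRead], dict[str, int]]:
    """Partition reads by barcode.

    Returns (assigned reads per sample, unassigned reads, per-stream
    counts).  Assigned reads have the barcode trimmed from sequence and
    quality; unassigned reads are untrimmed.
    """
    assigned: dict[str, list[FastqRead]] = {name: [] for name in spec.entries}
    unassigned: list[FastqRead] = []
    for name, read in _classified(reads, _Classifier(spec, max_mismatch)):
        if name is None:
            unassigned.append(read)
        else:
            assigned[name].append(read)
    counts = {name: len(rs) for name, rs in assigned.items()}
    counts[UNASSIGNED] = len(unassigned)
    return assigned, unassigned, counts


def demultiplex_to_files(fastq_path: str | os.PathLike, spec: BarcodeSpec,
                         outdir: str | os.PathLike, max_mismatch: int = 1
                         ) -> tuple[dict[str, str], dict[str, int]]:
    """Streaming variant writing one FASTQ per sample plus unassigned.fastq."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, f"{name}.fastq") for name in spec.entries}
    paths[UNASSIGNED] = os.path.join(outdir, f"{UNASSIGNED}.fastq")
    counts = dict.fromkeys(paths, 0)
    handles = {name: open(p, "w") for name, p in paths.items()}
    try:
        for name, (rid, seq, qual) in _classified(sio.iter_fastq(fastq_path),
                                                  _Classifier(spec, max_mismatch)):
            key = UNASSIGNED if name is None else name
            handles[key].write(f"@{rid}\n{seq}\n+\n{qual}\n")
            counts[key] += 1
    finally:
        for fh in handles.values():
            fh.close()
    return paths, counts


def write_count_report(counts: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("stream\tn_reads\n")
        for name, n in counts.items():
            fh.write(f"{name}\t{n}\n")
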