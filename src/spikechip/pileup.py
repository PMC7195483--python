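"""Duplicate-filtered, fragment-extended, SPMR-scaled coverage tracks.

The order of operations follows the quantification pipeline: duplicates
(same chromosome, 5' position and strand) are removed first, then each
surviving tag is extended to 150 bp in its 3' direction from the
sequenced 5' end, and per-base counts are scaled to signal per million
reads (SPMR) using the post-deduplication read count of the track's
genome.  Tracks round-trip through bedGraph and fixedStep wiggle at six
significant digits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .align import AlignmentRecord
from .errors import (ConfigError, DegenerateLibraryError, FormatError,
                     IncompatibilityError)
from .io import EXPERIMENTAL

RAW = "raw"
SPMR = "SPMR"
SPIKE_CALIBRATED = "spike-calibrated"
DEFAULT_EXTENSION = 150


@dataclass
class CoverageTrack:
    """Per-base float signal over one genome with scaling provenance."""

    genome_label: str
    values: dict[str, np.ndarray]
    provenance: str = RAW
    reads_used: int = 0
    meta: dict = field(default_factory=dict)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: v.size for c, v in self.values.items()}

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(self.genome_label,
                             {c: v.copy() for c, v in self.values.items()},
                             self.provenance, self.reads_used, dict(self.meta))


def deduplicate(alignments: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep one record per (chrom, 5' position, strand).

    Among duplicates the lexicographically smallest read_id is retained,
    which makes the result independent of input order.
    """
    ordered = sorted(alignments,
                     key=lambda r: (r.chrom, r.five_prime(), r.strand, r.read_id))
    kept: list[AlignmentRecord] = []
    last_key = None
    for rec in ordered:
        key = (rec.chrom, rec.five_prime(), rec.strand)
        if key != last_key:
            kept.append(rec)
            last_key = key
    return kept


def extend_and_pileup(alignments: Sequence[AlignmentRecord],
                      chrom_lengths: dict[str, int],
                      extension: int = DEFAULT_EXTENSION,
                      genome_label: str = EXPERIMENTAL) -> CoverageTrack:
    """Raw coverage from tags extended to ``extension`` bases 3' of their
    5' end: [start, start+ext) for "+", (5' - ext, 5'] for "-", truncated
    at chromosome bounds."""
    if extension <= 0:
        raise ConfigError("extension must be strictly positive")
    diffs = {c: np.zeros(length + 1, dtype=np.float64)
             for c, length in chrom_lengths.items()}
    n = 0
    for rec in alignments:
        if rec.chrom not in diffs:
            raise IncompatibilityError(f"record on unknown chromosome {rec.chrom!r}")
        length = chrom_lengths[rec.chrom]
        if rec.strand == "+":
            s = rec.start
            e = min(s + extension, length)
        else:
            fp = rec.five_prime()
            s = max(fp - extension + 1, 0)
            e = fp + 1
        if s < e:
            diffs[rec.chrom][s] += 1.0
            diffs[rec.chrom][e] -= 1.0
        n += 1
    values = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return CoverageTrack(genome_label=genome_label, values=values,
                         provenance=RAW, reads_used=n)


def spmr_scale(track: CoverageTrack) -> CoverageTrack:
    """Scale a raw track to signal per million reads."""
    if track.provenance != RAW:
        from .errors import ProvenanceError
        raise ProvenanceError(f"SPMR scaling expects a raw track, got "
                              f"{track.provenance!r}")
    if track.reads_used <= 0:
        raise DegenerateLibraryError("cannot SPMR-scale a track built from 0 reads")
    scale = 1e6 / track.reads_used
    return CoverageTrack(track.genome_label,
                         {c: v * scale for c, v in track.values.items()},
                         SPMR, track.reads_used, dict(track.meta))


def average_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Per-base arithmetic mean of technical-replicate tracks."""
    if len(tracks) < 2:
        raise IncompatibilityError("averaging requires at least two tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if t.genome_label != first.genome_label:
            raise IncompatibilityError("tracks are from different genomes")
        if t.provenance != first.provenance:
            raise IncompatibilityError(
                f"mixed provenance: {t.provenance!r} vs {first.provenance!r}")
        if t.chrom_lengths() != first.chrom_lengths():
            raise IncompatibilityError("tracks have different chromosome lengths")
    values = {c: np.mean([t.values[c] for t in tracks], axis=0)
              for c in first.values}
    return CoverageTrack(first.genome_label, values, first.provenance,
                         sum(t.reads_used for t in tracks))


# -- track serialization ------------------------------------------------------

def _header_line(track: CoverageTrack, fmt: str, name: str) -> str:
    ttype = "bedGraph" if fmt == "bedGraph" else "wiggle_0"
    return (f'track type={ttype} name="{name}" description="provenance='
            f'{track.provenance};reads_used={track.reads_used};'
            f'genome={track.genome_label}"\n')


def _parse_header(line: str) -> tuple[str, int, str]:
    import re
    m = re.search(r'provenance=([^;"]+);reads_used=(\d+);genome=([^;"]+)', line)
    if not m:
        return RAW, 0, EXPERIMENTAL
    return m.group(1), int(m.group(2)), m.group(3)


def write_track(track: CoverageTrack, path: str | os.PathLike,
                fmt: str = "bedGraph", name: str = "track") -> None:
    """Write bedGraph (run-length merged, zero rows omitted) or fixedStep
    wiggle (start=1, step=1, every base).  Values print at 6 significant
    digits."""
    if fmt not in ("bedGraph", "wiggle"):
        raise ConfigError(f"unknown track format {fmt!r}")
    with open(path, "w") as fh:
        fh.write(_header_line(track, fmt, name))
        for chrom, vals in track.values.items():
            if fmt == "bedGraph":
                if vals.size == 0:
                    continue
                edges = np.nonzero(np.diff(vals))[0]
                starts = np.concatenate([[0], edges + 1])
                ends = np.concatenate([edges + 1, [vals.size]])
                for s, e in zip(starts, ends):
                    v = vals[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
            else:
                fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                fh.write("".join(f"{v:.6g}\n" for v in vals))


def read_track(path: str | os.PathLike,
               chrom_lengths: dict[str, int] | None = None) -> CoverageTrack:
    """Read a track written by :func:`write_track` (format auto-detected).

    bedGraph does not record chromosome lengths, so supply
    ``chrom_lengths`` to recover trailing zero runs exactly.
    """
    provenance, reads_used, label = RAW, 0, EXPERIMENTAL
    wig_chrom: str | None = None
    wig_values: list[float] = []
    bg_rows: dict[str, list[tuple[int, int, float]]] = {}
    wig: dict[str, np.ndarray] = {}
    is_wiggle = False
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("track"):
                provenance, reads_used, label = _parse_header(line)
                is_wiggle = "wiggle_0" in line
                continue
            if line.startswith("fixedStep"):
                if wig_chrom is not None:
                    wig[wig_chrom] = np.array(wig_values)
                try:
                    fields = dict(kv.split("=") for kv in line.split()[1:])
                    wig_chrom = fields["chrom"]
                    if int(fields.get("start", 1)) != 1 or int(fields.get("step", 1)) != 1:
                        raise ValueError("only start=1 step=1 supported")
                except (ValueError, KeyError) as exc:
                    raise FormatError(str(exc), line=ln) from exc
                wig_values = []
                continue
            if is_wiggle or wig_chrom is not None:
                try:
                    wig_values.append(float(line))
                except ValueError as exc:
                    raise FormatError(f"bad wiggle value {line!r}", line=ln) from exc
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"expected 4 bedGraph columns, got {len(parts)}",
                                  line=ln)
            try:
                chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise FormatError(f"bad bedGraph row: {exc}", line=ln) from exc
            if e <= s or s < 0:
                raise FormatError(f"bad interval [{s}, {e})", line=ln)
            bg_rows.setdefault(chrom, []).append((s, e, v))
    if wig_chrom is not None:
        wig[wig_chrom] = np.array(wig_values)
    if wig:
        values = wig
    else:
        values = {}
        lengths = chrom_lengths or {c: rows[-1][1] for c, rows in bg_rows.items()}
        for chrom, length in lengths.items():
            arr = np.zeros(length, dtype=np.float64)
            for s, e, v in bg_rows.get(chrom, []):
                arr[s:e] = v
            values[chrom] = arr
    return CoverageTrack(label, values, provenance, reads_used)
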