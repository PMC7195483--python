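"""Unique exact-match placement of reads on two genomes.

The aligner mirrors the quantification pipeline's contract rather than a
general-purpose mapper: the first base of each read is excluded, the
remaining sequence is searched exactly on both strands, and only reads
with exactly one placement are kept ("multi-aligned reads" are dropped).
Reads are tried against the spike genome first; reads without a unique
spike placement are then tried against the experimental genome, which
makes exclusive assignment an operational property of the two-pass order.

The index is a sorted array of 2-bit-packed 20-mer seeds over the forward
strand; a query is located by binary search on its leading seed and
verified by full-length byte comparison, reverse-complement hits being
found by searching the reverse complement of the query.  External
alignments (SAM/BAM via pysam, or BED6) can be ingested instead for real
data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from . import io as sio
from .errors import FormatError, MalformedReadError
from .io import EXPERIMENTAL, SPIKE
from .simulate import Genome

DEFAULT_SEED_LENGTH = 20
MIN_READ_LENGTH = 21  # one excluded base + a full seed
_MAX_SEED_HITS = 256  # more seed hits than this is treated as multi-aligned

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_RC_BYTE = np.full(256, ord("N"), dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _RC_BYTE[_x] = _y


@dataclass(frozen=True)
class AlignmentRecord:
    """A uniquely placed read (0-based leftmost coordinate)."""

    read_id: str
    genome_label: str
    chrom: str
    start: int
    strand: str
    aligned_length: int

    @property
    def end(self) -> int:
        return self.start + self.aligned_length

    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class LibraryCounts:
    """Exclusive per-genome read counts of one library."""

    sample: str
    n_spike: int
    n_exp: int

    @property
    def total(self) -> int:
        return self.n_spike + self.n_exp


class GenomeIndex:
    """Seed-and-verify exact substring index over one genome."""

    def __init__(self, genome: Genome, seed_length: int = DEFAULT_SEED_LENGTH):
        self.genome = genome
        self.k = seed_length
        self.chrom_names = list(genome.chroms)
        lengths = np.array([len(genome.chroms[c]) for c in self.chrom_names],
                           dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        seq = "".join(genome.chroms[c] for c in self.chrom_names)
        self.seq_bytes = np.frombuffer(seq.encode(), dtype=np.uint8)
        kmers, positions = [], []
        k = self.k
        for ci in range(len(self.chrom_names)):
            lo, hi = int(self.offsets[ci]), int(self.offsets[ci + 1])
            codes = _CODE[self.seq_bytes[lo:hi]]
            if hi - lo < k:
                continue
            n = hi - lo - k + 1
            acc = np.zeros(n, dtype=np.uint64)
            for j in range(k):
                acc = (acc << np.uint64(2)) | codes[j:j + n].astype(np.uint64)
            bad = np.concatenate([[0], np.cumsum(codes > 3)])
            keep = (bad[k:] - bad[:-k]) == 0
            kmers.append(acc[keep])
            positions.append(np.nonzero(keep)[0].astype(np.int64) + lo)
        km = np.concatenate(kmers)
        pos = np.concatenate(positions)
        order = np.argsort(km, kind="stable")
        self.kmers = km[order]
        self.positions = pos[order]

    # -- low-level batch machinery -------------------------------------------

    def _seed_hits(self, bm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Full-length exact hits of every row of byte matrix ``bm``.

        Returns (read indices, global positions) of verified hits plus a
        boolean mask of reads whose seed was pathologically repetitive
        (treated as multi-aligned by the caller).
        """
        n, L = bm.shape
        k = self.k
        codes = _CODE[bm[:, :k]]
        valid = (codes < 4).all(axis=1)
        acc = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            acc = (acc << np.uint64(2)) | codes[:, j].astype(np.uint64)
        lo = np.searchsorted(self.kmers, acc, side="left")
        hi = np.searchsorted(self.kmers, acc, side="right")
        lo[~valid] = 0
        hi[~valid] = 0
        counts = hi - lo
        overflow = counts > _MAX_SEED_HITS
        counts[overflow] = 0
        total = int(counts.sum())
        if total == 0:
            return (np.empty(0, np.int64), np.empty(0, np.int64), overflow)
        ridx = np.repeat(np.arange(n), counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        cand = self.positions[np.repeat(lo, counts) + within]
        cid = np.searchsorted(self.offsets, cand, side="right") - 1
        inbounds = cand + L <= self.offsets[cid + 1]
        ridx, cand = ridx[inbounds], cand[inbounds]
        if ridx.size == 0:
            return (ridx, cand, overflow)
        windows = self.seq_bytes[cand[:, None] + np.arange(L)]
        match = (windows == bm[ridx]).all(axis=1)
        return ridx[match], cand[match], overflow

    def _global_to_local(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cid = np.searchsorted(self.offsets, pos, side="right") - 1
        return cid, pos - self.offsets[cid]

    def align_batch(self, seqs: Sequence[str]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Uniquely place already-trimmed, equal-length sequences.

        Returns (placed mask, chrom index, local start, plus-strand mask);
        entries of unplaced reads are undefined.
        """
        n = len(seqs)
        if n == 0:
            z = np.empty(0, dtype=np.int64)
            return np.empty(0, dtype=bool), z, z, np.empty(0, dtype=bool)
        L = len(seqs[0])
        bm = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, L)
        bm_rc = _RC_BYTE[bm][:, ::-1]
        rf, pf, of_f = self._seed_hits(bm)
        rr, pr, of_r = self._seed_hits(bm_rc)
        nf = np.bincount(rf, minlength=n)
        nr = np.bincount(rr, minlength=n)
        nhits = nf + nr
        nhits[of_f | of_r] = 2  # repetitive seed: never unique
        pos_f = np.zeros(n, dtype=np.int64)
        pos_f[rf] = pf
        pos_r = np.zeros(n, dtype=np.int64)
        pos_r[rr] = pr
        placed = nhits == 1
        plus = placed & (nf == 1)
        pos = np.where(plus, pos_f, pos_r)
        cid, local = self._global_to_local(pos)
        return placed, cid, local, plus

    # -- public queries -------------------------------------------------------

    def find(self, query: str) -> list[tuple[str, int, str]]:
        """All exact placements of ``query`` (length >= seed length) on
        either strand, as (chrom, leftmost start, strand)."""
        if len(query) < self.k:
            raise MalformedReadError(
                f"query length {len(query)} < seed length {self.k}")
        hits: list[tuple[str, int, str]] = []
        L = len(query)
        for seq, strand in ((query, "+"), (_rc(query), "-")):
            bm = np.frombuffer(seq.encode(), dtype=np.uint8).reshape(1, L)
            ridx, pos, overflow = self._seed_hits(bm)
            if overflow.any():  # fall back to a direct scan for repetitive seeds
                pos = _naive_find(self.seq_bytes, self.offsets, bm[0])
            for p in np.sort(pos):
                cid, local = self._global_to_local(np.array([p]))
                hits.append((self.chrom_names[int(cid[0])], int(local[0]), strand))
        return hits


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _naive_find(seq_bytes: np.ndarray, offsets: np.ndarray,
                query: np.ndarray) -> np.ndarray:
    L = query.size
    n = seq_bytes.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(L):
        ok &= seq_bytes[j:j + n] == query[j]
    pos = np.nonzero(ok)[0]
    cid = np.searchsorted(offsets, pos, side="right") - 1
    inb = pos + L <= offsets[cid + 1]
    return pos[inb]


def build_index(genome: Genome, seed_length: int = DEFAULT_SEED_LENGTH) -> GenomeIndex:
    return GenomeIndex(genome, seed_length)


def _check_alphabet(seq: str) -> None:
    if set(seq) - set("ACGTN"):
        raise MalformedReadError(
            f"read contains characters outside ACGTN: {sorted(set(seq) - set('ACGTN'))}")


def align_unique(read: str, index: GenomeIndex,
                 read_id: str = "") -> AlignmentRecord | None:
    """Place one read: first base excluded, exact match on both strands,
    returned only when the placement is unique."""
    if len(read) < MIN_READ_LENGTH:
        raise MalformedReadError(
            f"read length {len(read)} < minimum {MIN_READ_LENGTH}")
    _check_alphabet(read)
    trimmed = read[1:]
    placed, cid, local, plus = index.align_batch([trimmed])
    if not placed[0]:
        return None
    return AlignmentRecord(
        read_id=read_id, genome_label=index.genome.label,
        chrom=index.chrom_names[int(cid[0])], start=int(local[0]),
        strand="+" if plus[0] else "-", aligned_length=len(trimmed))


def assign_exclusive(reads: Iterable[tuple[str, str]], spike_index: GenomeIndex,
                     exp_index: GenomeIndex, sample: str = "sample",
                     chunk_size: int = 100_000
                     ) -> tuple[dict[str, list[AlignmentRecord]], LibraryCounts, dict]:
    """Sequential spike-first exclusive assignment.

    Each read is tried against the spike genome; reads without a unique
    spike placement are tried against the experimental genome; reads
    unique in neither are dropped.  Also reports how many spike-assigned
    reads would additionally have a unique experimental placement
    (cross-mappers), since the two-pass order silently resolves those.
    """
    records: dict[str, list[AlignmentRecord]] = {SPIKE: [], EXPERIMENTAL: []}
    stats = {"n_reads": 0, "n_dropped": 0, "n_cross_mappers": 0}

    def flush(ids: list[str], seqs: list[str]) -> None:
        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(seqs):
            by_len.setdefault(len(s), []).append(i)
        for length, idxs in by_len.items():
            trimmed = [seqs[i][1:] for i in idxs]
            sp, sc, sl, ss = spike_index.align_batch(trimmed)
            rest = [j for j, ok in enumerate(sp) if not ok]
            ep, ec, el, es = exp_index.align_batch([trimmed[j] for j in rest])
            # cross-mapper audit: spike winners that are also unique in experimental
            spike_won = [j for j, ok in enumerate(sp) if ok]
            xp, _, _, _ = exp_index.align_batch([trimmed[j] for j in spike_won])
            stats["n_cross_mappers"] += int(xp.sum())
            for j in spike_won:
                records[SPIKE].append(AlignmentRecord(
                    read_id=ids[idxs[j]], genome_label=SPIKE,
                    chrom=spike_index.chrom_names[int(sc[j])], start=int(sl[j]),
                    strand="+" if ss[j] else "-", aligned_length=length - 1))
            for m, j in enumerate(rest):
                if not ep[m]:
                    stats["n_dropped"] += 1
                    continue
                records[EXPERIMENTAL].append(AlignmentRecord(
                    read_id=ids[idxs[j]], genome_label=EXPERIMENTAL,
                    chrom=exp_index.chrom_names[int(ec[m])], start=int(el[m]),
                    strand="+" if es[m] else "-", aligned_length=length - 1))

    ids: list[str] = []
    seqs: list[str] = []
    for rid, seq in reads:
        if len(seq) < MIN_READ_LENGTH:
            raise MalformedReadError(
                f"read {rid!r} length {len(seq)} < minimum {MIN_READ_LENGTH}")
        stats["n_reads"] += 1
        ids.append(rid)
        seqs.append(seq)
        if len(ids) >= chunk_size:
            flush(ids, seqs)
            ids, seqs = [], []
    if ids:
        flush(ids, seqs)
    counts = LibraryCounts(sample=sample, n_spike=len(records[SPIKE]),
                           n_exp=len(records[EXPERIMENTAL]))
    return records, counts, stats


def read_alignments(path: str | os.PathLike, genome_label: str
                    ) -> list[AlignmentRecord]:
    """Ingest externally produced alignments (SAM/BAM or BED6).

    SAM/BAM: mapped, primary, non-duplicate records only; strand from
    flags; positions converted to 0-based.  BED6: strand from column 6.
    """
    path = os.fspath(path)
    if path.endswith((".sam", ".bam", ".cram")):
        mode = "rb" if path.endswith(".bam") else "r"
        records = []
        with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
            for rec in fh:
                if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                        or rec.is_duplicate):
                    continue
                length = rec.reference_length or rec.query_length
                records.append(AlignmentRecord(
                    read_id=rec.query_name, genome_label=genome_label,
                    chrom=rec.reference_name, start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    aligned_length=int(length)))
        return records
    if path.endswith(".bed"):
        return [AlignmentRecord(read_id=name, genome_label=genome_label,
                                chrom=chrom, start=start, strand=strand,
                                aligned_length=end - start)
                for chrom, start, end, name, _score, strand in sio.read_bed6(path)]
    raise FormatError(f"cannot infer alignment format from extension: {path}")


def write_alignments_bed(records: Iterable[AlignmentRecord],
                         path: str | os.PathLike) -> int:
    return sio.write_bed6(((r.chrom, r.start, r.end, r.read_id, "0", r.strand)
                           for r in records), path)
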