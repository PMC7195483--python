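"""Exact-match unique placement and sequential dual-genome assignment."""

import numpy as np
import pytest

from spikechip import align as al
from spikechip import simulate as sim
from spikechip.errors import FormatError, MalformedReadError
from spikechip.io import EXPERIMENTAL, SPIKE

from conftest import small_config


def random_genome(label, length, seed, n_chroms=1):
    cfg = small_config(seed=seed)
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms = {}
    per = length // n_chroms
    prefix = "chrE" if label == EXPERIMENTAL else "chrS"
    for i in range(n_chroms):
        chroms[f"{prefix}{i + 1}"] = bases[
            rng.integers(0, 4, per)].tobytes().decode()
    return sim.Genome(label, chroms)


def naive_align(read, genome):
    """Brute-force oracle: scan every position and strand for the trimmed
    read; unique hits only."""
    trimmed = read[1:]
    rc = sim.reverse_complement(trimmed)
    hits = []
    for chrom, seq in genome.chroms.items():
        for query, strand in ((trimmed, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                hits.append((chrom, start, strand))
                start = seq.find(query, start + 1)
    return hits[0] if len(hits) == 1 else None


@pytest.fixture(scope="module")
def indexed():
    genome = random_genome(EXPERIMENTAL, 30_000, seed=9)
    return genome, al.build_index(genome)


class TestIndexQueries:
    def test_unique_kmer_single_hit(self, indexed):
        genome, index = indexed
        query = genome.chroms["chrE1"][1000:1049]
        assert index.find(query) == [("chrE1", 1000, "+")]

    def test_reverse_complement_same_locus_minus(self, indexed):
        genome, index = indexed
        query = sim.reverse_complement(genome.chroms["chrE1"][1000:1049])
        assert index.find(query) == [("chrE1", 1000, "-")]

    def test_absent_query_no_hits(self, indexed):
        _genome, index = indexed
        assert index.find("A" * 49) == []

    def test_short_query_rejected(self, indexed):
        with pytest.raises(MalformedReadError):
            indexed[1].find("ACGTACGT")


class TestAlignUnique:
    def test_planted_read_recovered(self, indexed):
        genome, index = indexed
        read = genome.chroms["chrE1"][5000:5050]
        rec = al.align_unique(read, index, read_id="r1")
        assert rec == al.AlignmentRecord("r1", EXPERIMENTAL, "chrE1", 5001,
                                         "+", 49)

    def test_first_base_mismatch_still_placed(self, indexed):
        genome, index = indexed
        read = genome.chroms["chrE1"][5000:5050]
        flipped = ("C" if read[0] != "C" else "G") + read[1:]
        rec = al.align_unique(flipped, index)
        assert rec is not None and rec.start == 5001

    def test_internal_mismatch_not_placed(self, indexed):
        genome, index = indexed
        read = list(genome.chroms["chrE1"][5000:5050])
        read[25] = "C" if read[25] != "C" else "G"
        assert al.align_unique("".join(read), index) is None

    def test_multi_locus_read_dropped(self):
        seg = random_genome(EXPERIMENTAL, 2_000, seed=11).chroms["chrE1"]
        dup = seg[:60]
        genome = sim.Genome(EXPERIMENTAL, {"chrE1": seg + dup + seg[500:] + dup})
        index = al.build_index(genome)
        assert al.align_unique(dup[:50], index) is None

    def test_minus_strand_read_placed(self, indexed):
        genome, index = indexed
        read = sim.reverse_complement(genome.chroms["chrE1"][7000:7050])
        rec = al.align_unique(read, index)
        # trimming the 5' base of a minus-strand read drops its rightmost
        # genomic base, leaving the leftmost coordinate unchanged
        assert (rec.chrom, rec.start, rec.strand) == ("chrE1", 7000, "-")

    def test_errors(self, indexed):
        _genome, index = indexed
        with pytest.raises(MalformedReadError):
            al.align_unique("ACGT" * 3, index)  # too short
        with pytest.raises(MalformedReadError):
            al.align_unique("ACGU" * 10, index)  # bad alphabet

    def test_agrees_with_naive_scan(self, indexed):
        genome, index = indexed
        rng = np.random.default_rng(4)
        chrom = genome.chroms["chrE1"]
        reads = []
        for pos in rng.integers(0, len(chrom) - 50, size=120):
            read = chrom[pos:pos + 50]
            if rng.random() < 0.5:
                read = sim.reverse_complement(read)
            if rng.random() < 0.2:  # corrupt an internal base
                i = int(rng.integers(1, 50))
                read = read[:i] + "ACGT"[int(rng.integers(0, 4))] + read[i + 1:]
            reads.append(read)
        reads += ["".join("ACGT"[i] for i in rng.integers(0, 4, 50))
                  for _ in range(30)]
        for read in reads:
            rec = al.align_unique(read, index)
            expect = naive_align(read, genome)
            got = None if rec is None else (rec.chrom, rec.start, rec.strand)
            assert got == expect


class TestAssignExclusive:
    def test_planted_counts(self):
        spike = random_genome(SPIKE, 20_000, seed=21)
        exp = random_genome(EXPERIMENTAL, 60_000, seed=22)
        si, ei = al.build_index(spike), al.build_index(exp)
        reads = []
        for i in range(10):
            reads.append((f"s{i}", spike.chroms["chrS1"][100 * i:100 * i + 50]))
        for i in range(90):
            reads.append((f"e{i}", exp.chroms["chrE1"][200 * i:200 * i + 50]))
        records, counts, stats = al.assign_exclusive(reads, si, ei)
        assert (counts.n_spike, counts.n_exp) == (10, 90)
        assert stats["n_dropped"] == 0
        spike_ids = {r.read_id for r in records[SPIKE]}
        exp_ids = {r.read_id for r in records[EXPERIMENTAL]}
        assert not spike_ids & exp_ids

    def test_read_in_both_genomes_goes_to_spike(self):
        base_spike = random_genome(SPIKE, 10_000, seed=23).chroms["chrS1"]
        base_exp = random_genome(EXPERIMENTAL, 10_000, seed=24).chroms["chrE1"]
        shared = random_genome(EXPERIMENTAL, 1_000, seed=25).chroms["chrE1"][:60]
        spike = sim.Genome(SPIKE, {"chrS1": base_spike + shared})
        exp = sim.Genome(EXPERIMENTAL, {"chrE1": base_exp + shared})
        records, counts, stats = al.assign_exclusive(
            [("r1", shared[:50])], al.build_index(spike), al.build_index(exp))
        assert counts.n_spike == 1 and counts.n_exp == 0
        assert stats["n_cross_mappers"] == 1

    def test_spike_multimapper_unique_in_experimental(self):
        base_spike = random_genome(SPIKE, 10_000, seed=26).chroms["chrS1"]
        base_exp = random_genome(EXPERIMENTAL, 10_000, seed=27).chroms["chrE1"]
        shared = random_genome(EXPERIMENTAL, 1_000, seed=28).chroms["chrE1"][:60]
        spike = sim.Genome(SPIKE, {"chrS1": base_spike + shared + "AC" + shared})
        exp = sim.Genome(EXPERIMENTAL, {"chrE1": base_exp + shared})
        records, counts, _ = al.assign_exclusive(
            [("r1", shared[:50])], al.build_index(spike), al.build_index(exp))
        assert counts.n_spike == 0 and counts.n_exp == 1
        assert records[EXPERIMENTAL][0].start == 10_001


class TestReadAlignments:
    def test_sam_ingestion(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrE1\tLN:10000\n"
            "r1\t0\tchrE1\t100\t42\t49M\t*\t0\t0\t" + "A" * 49 + "\t*\n"
            "r2\t16\tchrE1\t200\t42\t49M\t*\t0\t0\t" + "A" * 49 + "\t*\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 49 + "\t*\n")
        recs = al.read_alignments(sam, EXPERIMENTAL)
        assert [(r.read_id, r.start, r.strand, r.aligned_length)
                for r in recs] == [("r1", 99, "+", 49), ("r2", 199, "-", 49)]

    def test_bed_ingestion(self, tmp_path):
        bed = tmp_path / "toy.bed"
        bed.write_text("chrI\t99\t148\tr1\t0\t-\n")
        rec, = al.read_alignments(bed, EXPERIMENTAL)
        assert (rec.chrom, rec.start, rec.strand, rec.aligned_length) == \
            ("chrI", 99, "-", 49)

    def test_malformed_bed_reports_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chrI\t99\t148\tr1\t0\t-\nchrI\tnope\t1\tr2\t0\t+\n")
        with pytest.raises(FormatError, match="line 2"):
            al.read_alignments(bed, EXPERIMENTAL)
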