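"""Synthetic dual-genome ChIP-seq experiments with known ground truth.

The generator emulates a spike-in calibrated histone-methylation ChIP-seq
design: an experimental (budding-yeast-like) genome carrying genes with
promoter-proximal enrichment that decays exponentially downstream of the
TSS, plus a spike-in (fission-yeast-like) genome whose chromatin is added
at a fixed mass fraction (10% by default) to every sample.  A "mutant"
sample is modelled as a global multiplicative reduction of ChIP efficiency
on the experimental genome only; the spike-in pull-down profile is pinned
to efficiency 1.0 in every sample, which is the premise that makes
spike-in calibration work.

Reads are error-free 50 bp single-end reads taken from the 5' end of
uniformly-stranded fragments of 200-500 bp, with an in-line sample barcode
prepended.  Read names encode the true origin (sample, genome, chromosome,
position, strand) so downstream stages can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import io as sio
from .errors import ConfigError, DegenerateProfileError, PlacementError
from .io import EXPERIMENTAL, SPIKE, FastqRead

# fixed stream tags so adding a sample never perturbs another stream
_STREAM_GENOME_EXP = 1
_STREAM_GENOME_SPIKE = 2
_STREAM_GENES = 3
_STREAM_SPIKE_GENES = 4
_STREAM_SAMPLE = 5

# enrichment extends at most this many decay lengths downstream of a TSS
ENRICHMENT_SPAN_DECAYS = 3

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = dict(zip("ACGTN", "TGCAN"))
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated library and of the shared experiment design.

    Genome/gene/enrichment fields describe the shared design and must be
    identical across the samples of one experiment; ``efficiency``,
    ``barcode`` and the read counts are per-sample.
    """

    exp_genome_length: int = 6_000_000
    spike_genome_length: int = 1_200_000
    n_chroms_exp: int = 3
    n_chroms_spike: int = 2
    n_genes: int = 260
    n_spike_genes: int | None = None  # default: same gene density as experimental
    min_gene_spacing: int = 6_000
    peak_amplitude: float = 8.0      # fold enrichment over background at the TSS
    decay_length: int = 500          # bp; exponential decay constant downstream of TSS
    background_rate: float = 1.0
    amplitude_sigma: float = 0.4     # lognormal sigma of per-gene amplitude variation
    efficiency: float = 1.0          # global ChIP efficiency, 1.0 for wild type
    spike_mass_fraction: float = 0.10
    frag_len_min: int = 200
    frag_len_max: int = 500
    read_length: int = 50
    n_ip_reads: int = 200_000
    n_input_reads: int = 200_000
    barcode: str = "ACGTAC"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.spike_mass_fraction < 1):
            raise ConfigError("spike_mass_fraction must be in (0, 1)")
        if not (0 < self.efficiency <= 1):
            raise ConfigError("efficiency must be in (0, 1]")
        if self.frag_len_min > self.frag_len_max:
            raise ConfigError("frag_len_min must be <= frag_len_max")
        if self.read_length > self.frag_len_min:
            raise ConfigError("read_length must be <= frag_len_min")
        for name in ("exp_genome_length", "spike_genome_length", "n_chroms_exp",
                     "n_chroms_spike", "n_genes", "min_gene_spacing", "decay_length",
                     "frag_len_min", "frag_len_max", "read_length",
                     "n_ip_reads", "n_input_reads"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.exp_genome_length // self.n_chroms_exp < self.read_length:
            raise ConfigError("experimental chromosomes shorter than read_length")
        if self.spike_genome_length // self.n_chroms_spike < self.read_length:
            raise ConfigError("spike chromosomes shorter than read_length")
        if self.exp_genome_length // self.n_chroms_exp < self.frag_len_max:
            raise ConfigError("experimental chromosomes shorter than frag_len_max")
        if self.spike_genome_length // self.n_chroms_spike < self.frag_len_max:
            raise ConfigError("spike chromosomes shorter than frag_len_max")
        if self.background_rate < 0 or self.peak_amplitude < 0:
            raise ConfigError("rates and amplitudes must be nonnegative")
        if set(self.barcode) - set("ACGT"):
            raise ConfigError("barcode must be over {A,C,G,T}")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def spike_gene_count(self) -> int:
        if self.n_spike_genes is not None:
            return self.n_spike_genes
        return max(1, round(self.n_genes * self.spike_genome_length
                            / self.exp_genome_length))

    # fields that define the shared experiment design
    _SHARED = ("exp_genome_length", "spike_genome_length", "n_chroms_exp",
               "n_chroms_spike", "n_genes", "n_spike_genes", "min_gene_spacing",
               "peak_amplitude", "decay_length", "background_rate",
               "amplitude_sigma", "spike_mass_fraction", "frag_len_min",
               "frag_len_max", "read_length", "seed")

    def shared_design(self) -> tuple:
        return tuple(getattr(self, f) for f in self._SHARED)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class Genome:
    """Named chromosome sequences for one genome (experimental or spike)."""

    label: str
    chroms: dict[str, str]

    def __post_init__(self):
        if self.label not in (EXPERIMENTAL, SPIKE):
            raise ConfigError(f"genome label must be experimental/spike, got {self.label!r}")
        if not self.chroms:
            raise ConfigError("genome has no chromosomes")
        for name, seq in self.chroms.items():
            if not seq or set(seq) - set("ACGTN"):
                raise ConfigError(f"chromosome {name!r} has an invalid alphabet")

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())


@dataclass(frozen=True)
class GeneAnnotation:
    """A transcriptional unit anchored at its TSS.

    ``amplitude`` is the gene's own fold-enrichment at the TSS (ground
    truth of the simulator); ``None`` means "use the config default".
    """

    id: str
    chrom: str
    tss: int
    strand: str
    amplitude: float | None = None


@dataclass
class TruthRecord:
    """Ground truth of one simulated sample; round-trips through JSON."""

    sample: str
    kind: str                    # "IP" or "input"
    efficiency: float
    spike_mass_fraction: float
    n_reads: int
    barcode: str
    seed: int
    background_rate: float
    decay_length: int
    peak_amplitude: float
    p_spike_expected: float      # expected spike read fraction after renormalization
    mean_weight_exp: float
    mean_weight_spike: float
    genes: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(**d)


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


def _sample_rng(seed: int, sample_name: str) -> np.random.Generator:
    return _rng(seed, _STREAM_SAMPLE, zlib.crc32(sample_name.encode()))


def _random_chroms(rng: np.random.Generator, prefix: str, total: int,
                   n_chroms: int) -> dict[str, str]:
    lengths = [total // n_chroms] * n_chroms
    lengths[-1] += total % n_chroms
    chroms = {}
    for i, length in enumerate(lengths, start=1):
        draws = rng.integers(0, 4, size=length)
        chroms[f"{prefix}{i}"] = _BASES[draws].tobytes().decode()
    return chroms


def make_genomes(config: SimConfig) -> tuple[Genome, Genome]:
    """Generate the experimental and spike genomes from distinct RNG streams."""
    config.validate()
    exp = Genome(EXPERIMENTAL, _random_chroms(
        _rng(config.seed, _STREAM_GENOME_EXP), "chrE", config.exp_genome_length,
        config.n_chroms_exp))
    spike = Genome(SPIKE, _random_chroms(
        _rng(config.seed, _STREAM_GENOME_SPIKE), "chrS", config.spike_genome_length,
        config.n_chroms_spike))
    return exp, spike


def make_geneset(genome: Genome, n_genes: int, min_gene_spacing: int, seed: int, *,
                 clearance: int = 1500, peak_amplitude: float = 1.0,
                 amplitude_sigma: float = 0.0, id_prefix: str = "g",
                 stream: int = _STREAM_GENES) -> list[GeneAnnotation]:
    """Place ``n_genes`` TSSs with pairwise spacing and downstream clearance.

    Every gene keeps ``clearance`` bases between its TSS and the chromosome
    end in the gene's direction so a full TSS-anchored window always fits.
    """
    rng = _rng(seed, stream)
    names = list(genome.chroms)
    lengths = np.array([len(genome.chroms[c]) for c in names], dtype=float)
    probs = lengths / lengths.sum()
    placed: dict[str, list[int]] = {c: [] for c in names}
    genes: list[tuple[str, int, str]] = []
    max_tries = 200 * n_genes + 1000
    tries = 0
    while len(genes) < n_genes:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n_genes} genes with spacing {min_gene_spacing} "
                f"after {tries} attempts")
        tries += 1
        chrom = names[rng.choice(len(names), p=probs)]
        length = len(genome.chroms[chrom])
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        lo, hi = (0, length - clearance) if strand == "+" else (clearance - 1, length - 1)
        if hi <= lo:
            continue
        tss = int(rng.integers(lo, hi + 1))
        if any(abs(tss - t) < min_gene_spacing for t in placed[chrom]):
            continue
        placed[chrom].append(tss)
        genes.append((chrom, tss, strand))
    order = {c: i for i, c in enumerate(names)}
    genes.sort(key=lambda g: (order[g[0]], g[1]))
    amps = peak_amplitude * rng.lognormal(0.0, amplitude_sigma, size=n_genes) \
        if amplitude_sigma > 0 else np.full(n_genes, peak_amplitude)
    width = max(4, len(str(n_genes)))
    return [GeneAnnotation(f"{id_prefix}{i + 1:0{width}d}", chrom, tss, strand,
                           float(amps[i]))
            for i, (chrom, tss, strand) in enumerate(genes)]


def make_spike_geneset(spike_genome: Genome, config: SimConfig) -> list[GeneAnnotation]:
    """Pseudo-genes on the spike genome; identical in every sample."""
    return make_geneset(spike_genome, config.spike_gene_count(),
                        config.min_gene_spacing, config.seed,
                        clearance=ENRICHMENT_SPAN_DECAYS * config.decay_length,
                        peak_amplitude=config.peak_amplitude,
                        amplitude_sigma=config.amplitude_sigma,
                        id_prefix="sp", stream=_STREAM_SPIKE_GENES)


def enrichment_weight(position: int, chrom: str, gene_set: list[GeneAnnotation],
                      config: SimConfig, efficiency: float | None = None) -> float:
    """Pull-down weight at one base.

    weight = background + efficiency * amplitude * exp(-d / decay_length)
    where d >= 0 is the strand-oriented distance to the nearest upstream
    TSS within ENRICHMENT_SPAN_DECAYS decay lengths; background elsewhere.
    """
    eff = config.efficiency if efficiency is None else efficiency
    span = ENRICHMENT_SPAN_DECAYS * config.decay_length
    best_d, best_amp = None, 0.0
    for gene in gene_set:
        if gene.chrom != chrom:
            continue
        d = position - gene.tss if gene.strand == "+" else gene.tss - position
        if 0 <= d < span and (best_d is None or d < best_d):
            best_d = d
            best_amp = gene.amplitude if gene.amplitude is not None \
                else config.peak_amplitude
    if best_d is None:
        return config.background_rate
    return config.background_rate + eff * best_amp * float(
        np.exp(-best_d / config.decay_length))


def enrichment_track(genome: Genome, gene_set: list[GeneAnnotation],
                     config: SimConfig,
                     efficiency: float | None = None) -> dict[str, np.ndarray]:
    """Vectorized per-base weights for a whole genome (same model as
    :func:`enrichment_weight`, nearest-TSS rule included)."""
    eff = config.efficiency if efficiency is None else efficiency
    span = ENRICHMENT_SPAN_DECAYS * config.decay_length
    tracks: dict[str, np.ndarray] = {}
    for chrom, seq in genome.chroms.items():
        length = len(seq)
        w = np.full(length, config.background_rate, dtype=np.float64)
        dmin = np.full(length, np.iinfo(np.int64).max, dtype=np.int64)
        for gene in gene_set:
            if gene.chrom != chrom:
                continue
            amp = gene.amplitude if gene.amplitude is not None else config.peak_amplitude
            if gene.strand == "+":
                n = min(span, length - gene.tss)
                if n <= 0:
                    continue
                pos = gene.tss + np.arange(n)
            else:
                n = min(span, gene.tss + 1)
                if n <= 0:
                    continue
                pos = gene.tss - np.arange(n)
            d = np.arange(n)
            closer = d < dmin[pos]
            sel = pos[closer]
            w[sel] = config.background_rate + eff * amp * np.exp(
                -d[closer] / config.decay_length)
            dmin[sel] = d[closer]
        tracks[chrom] = w
    return tracks


def _uniform_track(genome: Genome) -> dict[str, np.ndarray]:
    return {c: np.ones(len(s), dtype=np.float64) for c, s in genome.chroms.items()}


def _mean_weight(tracks: dict[str, np.ndarray]) -> float:
    total = sum(float(v.sum()) for v in tracks.values())
    n = sum(v.size for v in tracks.values())
    return total / n


def _draw_positions(rng: np.random.Generator, tracks: dict[str, np.ndarray],
                    k: int) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Inverse-CDF draw of ``k`` midpoints proportional to per-base weight."""
    names = list(tracks)
    lengths = np.array([tracks[c].size for c in names])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    cumw = np.cumsum(np.concatenate([tracks[c] for c in names]))
    total = cumw[-1]
    if total <= 0:
        raise DegenerateProfileError("enrichment profile has zero total weight")
    u = rng.random(k) * total
    flat = np.searchsorted(cumw, u, side="right")
    chrom_idx = np.searchsorted(offsets, flat, side="right") - 1
    local = flat - offsets[chrom_idx]
    return names, chrom_idx, local


def read_id(sample: str, serial: int, genome_label: str, chrom: str,
            leftmost: int, strand: str, frag_len: int) -> str:
    """Encode a read's true origin in its FASTQ id."""
    return f"{sample}:{serial:07d}|{genome_label}|{chrom}|{leftmost}|{strand}|{frag_len}"


def parse_read_id(rid: str) -> dict:
    head, genome_label, chrom, leftmost, strand, frag_len = rid.split("|")
    sample, serial = head.rsplit(":", 1)
    return {"sample": sample, "serial": int(serial), "genome": genome_label,
            "chrom": chrom, "leftmost": int(leftmost), "strand": strand,
            "frag_len": int(frag_len)}


def expected_spike_fraction(config: SimConfig, sample_kind: str,
                            mean_weight_exp: float,
                            mean_weight_spike: float) -> float:
    """Spike read fraction after renormalizing pull-down masses.

    Input libraries sample chromatin uniformly, so the fraction is the
    spike mass fraction itself; IP libraries weight each genome's mass by
    its mean pull-down weight.
    """
    s = config.spike_mass_fraction
    if sample_kind == "input":
        return s
    ms = s * mean_weight_spike
    me = (1.0 - s) * mean_weight_exp
    return ms / (ms + me)


def simulate_sample(config: SimConfig, genomes: tuple[Genome, Genome],
                    gene_set: list[GeneAnnotation], sample_kind: str, *,
                    sample_name: str = "sample",
                    spike_gene_set: list[GeneAnnotation] | None = None,
                    ) -> tuple[list[FastqRead], TruthRecord]:
    """Simulate one barcoded library (IP or input).

    Fragments pick a genome by spike-mass-weighted pull-down, a midpoint by
    inverse CDF over the per-base enrichment weights (uniform for input
    samples), a length uniform on [frag_len_min, frag_len_max] and a strand
    uniformly; the read is the first ``read_length`` bases from the 5' end
    of the chosen strand, with the barcode prepended.
    """
    config.validate()
    if sample_kind not in ("IP", "input"):
        raise ConfigError(f"sample_kind must be IP or input, got {sample_kind!r}")
    exp_genome, spike_genome = genomes
    if spike_gene_set is None:
        spike_gene_set = make_spike_geneset(spike_genome, config)

    if sample_kind == "IP":
        exp_tracks = enrichment_track(exp_genome, gene_set, config)
        spike_tracks = enrichment_track(spike_genome, spike_gene_set, config,
                                        efficiency=1.0)  # spike chromatin is invariant
    else:
        exp_tracks = _uniform_track(exp_genome)
        spike_tracks = _uniform_track(spike_genome)

    mean_exp = _mean_weight(exp_tracks)
    mean_spike = _mean_weight(spike_tracks)
    if mean_exp <= 0 or mean_spike <= 0:
        raise DegenerateProfileError("enrichment profile has zero total weight")
    p_spike = expected_spike_fraction(config, sample_kind, mean_exp, mean_spike)

    n = config.n_ip_reads if sample_kind == "IP" else config.n_input_reads
    rng = _sample_rng(config.seed, sample_name)
    is_spike = rng.random(n) < p_spike
    frag_lens = rng.integers(config.frag_len_min, config.frag_len_max + 1, size=n)
    minus = rng.integers(0, 2, size=n).astype(bool)

    chrom_names = np.empty(n, dtype=object)
    starts = np.empty(n, dtype=np.int64)
    for genome, tracks, mask in ((spike_genome, spike_tracks, is_spike),
                                 (exp_genome, exp_tracks, ~is_spike)):
        k = int(mask.sum())
        if k == 0:
            continue
        names, cidx, mids = _draw_positions(rng, tracks, k)
        lens = frag_lens[mask]
        clens = np.array([len(genome.chroms[c]) for c in names])[cidx]
        s = np.clip(mids - lens // 2, 0, clens - lens)
        chrom_names[mask] = np.array(names, dtype=object)[cidx]
        starts[mask] = s

    reads: list[FastqRead] = []
    R = config.read_length
    qual = "I" * (len(config.barcode) + R)
    label_of = {True: SPIKE, False: EXPERIMENTAL}
    chrom_seq = {**{c: s for c, s in spike_genome.chroms.items()},
                 **{c: s for c, s in exp_genome.chroms.items()}}
    for i in range(n):
        chrom = chrom_names[i]
        start = int(starts[i])
        flen = int(frag_lens[i])
        if minus[i]:
            left = start + flen - R
            seq = reverse_complement(chrom_seq[chrom][left:left + R])
            strand = "-"
        else:
            left = start
            seq = chrom_seq[chrom][left:left + R]
            strand = "+"
        rid = read_id(sample_name, i, label_of[bool(is_spike[i])], chrom, left,
                      strand, flen)
        reads.append((rid, config.barcode + seq, qual))

    truth = TruthRecord(
        sample=sample_name, kind=sample_kind, efficiency=config.efficiency,
        spike_mass_fraction=config.spike_mass_fraction, n_reads=n,
        barcode=config.barcode, seed=config.seed,
        background_rate=config.background_rate, decay_length=config.decay_length,
        peak_amplitude=config.peak_amplitude, p_spike_expected=p_spike,
        mean_weight_exp=mean_exp, mean_weight_spike=mean_spike,
        genes=[dataclasses.asdict(g) for g in gene_set])
    return reads, truth


@dataclass(frozen=True)
class SampleSpec:
    """One sample of a multiplexed experiment."""

    name: str
    kind: str  # "IP" or "input"
    config: SimConfig


def simulate_experiment(samples: list[SampleSpec],
                        outdir: str | os.PathLike) -> dict[str, str]:
    """Simulate a multiplexed experiment and write FASTA/BED/FASTQ/JSON.

    All samples must share the experiment design (genomes, gene set, seed)
    and carry distinct, equal-length barcodes.  Returns a path manifest.
    """
    if not samples:
        raise ConfigError("no samples to simulate")
    names = [s.name for s in samples]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate sample names")
    barcodes = [s.config.barcode for s in samples]
    if len(set(barcodes)) != len(barcodes):
        raise ConfigError("duplicate barcodes across samples")
    if len({len(b) for b in barcodes}) != 1:
        raise ConfigError("barcodes must all have the same length")
    base = samples[0].config
    for s in samples[1:]:
        if s.config.shared_design() != base.shared_design():
            raise ConfigError(
                f"sample {s.name!r} does not share the experiment design")

    exp_genome, spike_genome = make_genomes(base)
    gene_set = make_geneset(exp_genome, base.n_genes, base.min_gene_spacing,
                            base.seed, peak_amplitude=base.peak_amplitude,
                            amplitude_sigma=base.amplitude_sigma)
    spike_genes = make_spike_geneset(spike_genome, base)

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "exp_genome": os.path.join(outdir, "exp_genome.fa"),
        "spike_genome": os.path.join(outdir, "spike_genome.fa"),
        "genes": os.path.join(outdir, "genes.bed"),
        "fastq": os.path.join(outdir, "multiplexed.fastq"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    sio.write_fasta(exp_genome.chroms, paths["exp_genome"])
    sio.write_fasta(spike_genome.chroms, paths["spike_genome"])
    sio.write_bed6([(g.chrom, g.tss, g.tss + 1, g.id, "0", g.strand)
                    for g in gene_set], paths["genes"])

    per_sample: list[list[FastqRead]] = []
    truths: dict[str, dict] = {}
    for spec in samples:
        reads, truth = simulate_sample(
            spec.config, (exp_genome, spike_genome), gene_set, spec.kind,
            sample_name=spec.name, spike_gene_set=spike_genes)
        per_sample.append(reads)
        truths[spec.name] = truth.to_dict()

    # round-robin interleave so the multiplexed file mixes samples
    def interleaved():
        for group in itertools.zip_longest(*per_sample):
            for read in group:
                if read is not None:
                    yield read

    sio.write_fastq(interleaved(), paths["fastq"])

    truth_doc = {
        "seed": base.seed,
        "config": base.to_dict(),
        "samples": truths,
        "sample_order": names,
        "genes": [dataclasses.asdict(g) for g in gene_set],
        "spike_genes": [dataclasses.asdict(g) for g in spike_genes],
        "genome_lengths": {EXPERIMENTAL: exp_genome.lengths(),
                           SPIKE: spike_genome.lengths()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
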