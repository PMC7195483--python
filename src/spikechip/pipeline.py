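"""End-to-end orchestration: simulate -> demux -> assign -> normalize ->
pileup -> metagene, from one declarative YAML configuration.

Each stage writes its artifacts under the output directory and is skipped
on rerun when its outputs already exist, so deleting downstream artifacts
and rerunning regenerates only those.  A JSON manifest lists every
artifact with a checksum and the fully resolved parameter set; reruns of
an identical configuration produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import align as al
from . import demux as dx
from . import io as sio
from . import metagene as mg
from . import normalize as nm
from . import pileup as pl
from . import simulate as sim
from .errors import ConfigError, StageError
from .io import EXPERIMENTAL, SPIKE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleRow:
    name: str
    barcode: str
    kind: str                       # "IP" or "input"
    condition: str
    replicate: int = 1
    input_sample: str | None = None  # required for IP samples
    efficiency: float = 1.0          # used in simulate mode only
    n_reads: int | None = None       # used in simulate mode only


@dataclass
class RunConfig:
    outdir: str
    samples: list[SampleRow]
    seed: int = 0
    simulate: dict | None = None     # SimConfig field overrides
    inputs: dict | None = None       # paths: exp_genome, spike_genome, genes, fastq
    mismatch: int = 1
    extension: int = pl.DEFAULT_EXTENSION
    window: int = mg.DEFAULT_WINDOW
    bin_size: int = mg.DEFAULT_BIN_SIZE
    order_by: str | None = None      # reference condition for row ordering
    track_format: str = "bedGraph"

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for row in self.samples:
            if row.kind == "IP" and row.condition not in seen:
                seen.append(row.condition)
        return seen

    def params_dict(self) -> dict:
        return {"mismatch": self.mismatch, "extension": self.extension,
                "window": self.window, "bin_size": self.bin_size,
                "order_by": self.order_by or (self.conditions() or [None])[0],
                "seed": self.seed, "track_format": self.track_format}


def validate_config(source: str | os.PathLike | dict) -> RunConfig:
    """Parse and validate a run configuration; every violation is reported
    with its field path."""
    if isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            try:
                doc = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ConfigError(f"unparseable YAML: {exc}") from exc
        if not isinstance(doc, dict):
            raise ConfigError("config root must be a mapping")

    errors: list[str] = []
    params = doc.get("params", {}) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"samples"}
    for key in doc:
        if key not in known | {"params", "samples"}:
            errors.append(f"{key}: unknown top-level field")
    for key in params:
        if key not in {"mismatch", "extension", "window", "bin_size",
                       "order_by", "track_format"}:
            errors.append(f"params.{key}: unknown parameter")

    rows: list[SampleRow] = []
    for i, raw in enumerate(doc.get("samples", []) or []):
        path = f"samples[{i}]"
        try:
            rows.append(SampleRow(**raw))
        except TypeError as exc:
            errors.append(f"{path}: {exc}")
            continue
    names = [r.name for r in rows]
    if not rows:
        errors.append("samples: at least one sample is required")
    if len(set(names)) != len(names):
        errors.append("samples: duplicate sample names")
    if len({r.barcode for r in rows}) != len(rows):
        errors.append("samples: duplicate barcodes")
    for i, row in enumerate(rows):
        path = f"samples[{i}]"
        if row.kind not in ("IP", "input"):
            errors.append(f"{path}.kind: must be IP or input, got {row.kind!r}")
        if row.kind == "IP":
            if row.input_sample is None:
                errors.append(f"{path}.input_sample: required for IP samples")
            elif row.input_sample not in names:
                errors.append(f"{path}.input_sample: {row.input_sample!r} "
                              "does not name a sample")
            else:
                ref = rows[names.index(row.input_sample)]
                if ref.kind != "input":
                    errors.append(f"{path}.input_sample: {row.input_sample!r} "
                                  "is not an input sample")
        if not (0 < row.efficiency <= 1):
            errors.append(f"{path}.efficiency: must be in (0, 1]")

    cfg = RunConfig(
        outdir=doc.get("outdir", "spikechip_out"), samples=rows,
        seed=int(doc.get("seed", 0)), simulate=doc.get("simulate"),
        inputs=doc.get("inputs"),
        mismatch=int(params.get("mismatch", 1)),
        extension=int(params.get("extension", pl.DEFAULT_EXTENSION)),
        window=int(params.get("window", mg.DEFAULT_WINDOW)),
        bin_size=int(params.get("bin_size", mg.DEFAULT_BIN_SIZE)),
        order_by=params.get("order_by"),
        track_format=params.get("track_format", "bedGraph"))

    if cfg.window % cfg.bin_size != 0:
        errors.append(f"params.window: {cfg.window} not divisible by "
                      f"bin_size {cfg.bin_size}")
    if cfg.mismatch < 0 or cfg.extension <= 0:
        errors.append("params: mismatch must be >= 0 and extension > 0")
    if (cfg.simulate is None) == (cfg.inputs is None):
        errors.append("exactly one of `simulate:` or `inputs:` must be given")
    if cfg.inputs is not None:
        for key in ("exp_genome", "spike_genome", "genes", "fastq"):
            if key not in cfg.inputs:
                errors.append(f"inputs.{key}: required")
    if cfg.order_by is not None and cfg.order_by not in cfg.conditions():
        errors.append(f"params.order_by: {cfg.order_by!r} is not an IP condition")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _exists(*paths: str) -> bool:
    return all(os.path.exists(p) for p in paths)


class _Stage:
    """Context manager that drops a .failed marker when a stage raises."""

    def __init__(self, outdir: str, stage: str, sample: str | None = None):
        self.outdir, self.stage, self.sample = outdir, stage, sample

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            tag = self.stage if self.sample is None else f"{self.stage}.{self.sample}"
            marker = os.path.join(self.outdir, f"{tag}.failed")
            with open(marker, "w") as fh:
                fh.write(f"{exc_type.__name__}: {exc}\n")
            raise StageError(self.stage, self.sample) from exc
        return False


def run_pipeline(config: RunConfig | dict | str | os.PathLike,
                 force: bool = False) -> dict:
    """Run every stage; returns (and writes) the output manifest."""
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    out = config.outdir
    for sub in ("sim", "demux", "align", "normalize", "tracks", "matrix"):
        os.makedirs(os.path.join(out, sub), exist_ok=True)

    # --- simulate or locate inputs ------------------------------------------
    with _Stage(out, "simulate"):
        if config.simulate is not None:
            base = sim.SimConfig(**{**config.simulate, "seed": config.seed})
            specs = []
            for row in config.samples:
                overrides: dict = {"barcode": row.barcode,
                                   "efficiency": row.efficiency if row.kind == "IP" else 1.0}
                if row.n_reads is not None:
                    key = "n_ip_reads" if row.kind == "IP" else "n_input_reads"
                    overrides[key] = row.n_reads
                specs.append(sim.SampleSpec(row.name, row.kind,
                                            base.replace(**overrides)))
            simdir = os.path.join(out, "sim")
            paths = {k: os.path.join(simdir, v) for k, v in (
                ("exp_genome", "exp_genome.fa"), ("spike_genome", "spike_genome.fa"),
                ("genes", "genes.bed"), ("fastq", "multiplexed.fastq"),
                ("truth", "truth.json"))}
            if force or not _exists(*paths.values()):
                paths = sim.simulate_experiment(specs, simdir)
        else:
            paths = dict(config.inputs)

    exp_genome = sim.Genome(EXPERIMENTAL, sio.read_fasta(paths["exp_genome"]))
    spike_genome = sim.Genome(SPIKE, sio.read_fasta(paths["spike_genome"]))
    genes = [sim.GeneAnnotation(name, chrom, start, strand)
             for chrom, start, _end, name, _score, strand
             in sio.read_bed6(paths["genes"])]

    # --- demultiplex ---------------------------------------------------------
    demux_dir = os.path.join(out, "demux")
    spec = dx.BarcodeSpec({row.name: row.barcode for row in config.samples})
    demux_paths = {row.name: os.path.join(demux_dir, f"{row.name}.fastq")
                   for row in config.samples}
    demux_counts_path = os.path.join(demux_dir, "counts.tsv")
    with _Stage(out, "demux"):
        if force or not _exists(demux_counts_path, *demux_paths.values()):
            logger.info("demultiplexing %s", paths["fastq"])
            _, counts = dx.demultiplex_to_files(paths["fastq"], spec, demux_dir,
                                                config.mismatch)
            dx.write_count_report(counts, demux_counts_path)

    # --- align and assign ----------------------------------------------------
    align_dir = os.path.join(out, "align")
    counts_path = os.path.join(align_dir, "counts.tsv")
    bed_paths = {row.name: {
        EXPERIMENTAL: os.path.join(align_dir, f"{row.name}.experimental.bed"),
        SPIKE: os.path.join(align_dir, f"{row.name}.spike.bed")}
        for row in config.samples}
    need_align = force or not _exists(
        counts_path, *(p for d in bed_paths.values() for p in d.values()))
    lib_counts: dict[str, al.LibraryCounts] = {}
    if need_align:
        with _Stage(out, "align"):
            spike_index = al.build_index(spike_genome)
            exp_index = al.build_index(exp_genome)
            rows_out = []
            for row in config.samples:
                logger.info("assigning reads of sample %s", row.name)
                reads = ((rid, seq) for rid, seq, _q
                         in sio.iter_fastq(demux_paths[row.name]))
                records, counts, stats = al.assign_exclusive(
                    reads, spike_index, exp_index, sample=row.name)
                al.write_alignments_bed(records[EXPERIMENTAL],
                                        bed_paths[row.name][EXPERIMENTAL])
                al.write_alignments_bed(records[SPIKE], bed_paths[row.name][SPIKE])
                lib_counts[row.name] = counts
                rows_out.append((row.name, counts, stats))
            with open(counts_path, "w") as fh:
                fh.write("sample\tn_spike\tn_exp\tn_reads\tn_dropped\t"
                         "n_cross_mappers\n")
                for name, counts, stats in rows_out:
                    fh.write(f"{name}\t{counts.n_spike}\t{counts.n_exp}\t"
                             f"{stats['n_reads']}\t{stats['n_dropped']}\t"
                             f"{stats['n_cross_mappers']}\n")
    else:
        with open(counts_path) as fh:
            fh.readline()
            for line in fh:
                parts = line.split("\t")
                lib_counts[parts[0]] = al.LibraryCounts(
                    parts[0], int(parts[1]), int(parts[2]))

    # --- normalization factors ----------------------------------------------
    factors_path = os.path.join(out, "normalize", "factors.tsv")
    ip_rows = [r for r in config.samples if r.kind == "IP"]
    with _Stage(out, "normalize"):
        if force or not _exists(factors_path):
            report = []
            for row in ip_rows:
                f = nm.norm_factor(lib_counts[row.input_sample],
                                   lib_counts[row.name])
                report.append((lib_counts[row.input_sample],
                               lib_counts[row.name], f))
            nm.write_factor_report(report, factors_path)
        factors = nm.read_factor_report(factors_path)

    # --- pileup tracks -------------------------------------------------------
    tracks_dir = os.path.join(out, "tracks")
    exp_lengths = exp_genome.lengths()
    ext = "bedgraph" if config.track_format == "bedGraph" else "wig"
    track_path = lambda name, stage: os.path.join(tracks_dir, f"{name}.{stage}.{ext}")
    sample_tracks: dict[str, dict[str, pl.CoverageTrack]] = {}
    for row in config.samples:
        wanted = ["raw", "spmr"] + (["calibrated"] if row.kind == "IP" else [])
        files = {stage: track_path(row.name, stage) for stage in wanted}
        with _Stage(out, "pileup", row.name):
            if force or not _exists(*files.values()):
                recs = al.read_alignments(bed_paths[row.name][EXPERIMENTAL],
                                          EXPERIMENTAL)
                deduped = pl.deduplicate(recs)
                raw = pl.extend_and_pileup(deduped, exp_lengths, config.extension)
                spmr = pl.spmr_scale(raw)
                tracks = {"raw": raw, "spmr": spmr}
                if row.kind == "IP":
                    tracks["calibrated"] = nm.apply_factor(spmr, factors[row.name])
                for stage, tr in tracks.items():
                    pl.write_track(tr, files[stage], config.track_format,
                                   name=f"{row.name}.{stage}")
            # downstream stages consume the serialized form so that resumed
            # and fresh runs produce byte-identical artifacts
            tracks = {stage: pl.read_track(p, exp_lengths)
                      for stage, p in files.items()}
        sample_tracks[row.name] = tracks

    # --- per-condition averaging and metagene --------------------------------
    matrix_dir = os.path.join(out, "matrix")
    conditions = config.conditions()
    order_ref = config.order_by or (conditions[0] if conditions else None)
    cond_tracks: dict[str, pl.CoverageTrack] = {}
    with _Stage(out, "metagene"):
        for cond in conditions:
            members = [sample_tracks[r.name]["calibrated"]
                       for r in ip_rows if r.condition == cond]
            track = members[0] if len(members) == 1 else pl.average_tracks(members)
            cond_tracks[cond] = track
            cpath = track_path(f"condition.{cond}", "calibrated")
            if force or not _exists(cpath):
                pl.write_track(track, cpath, config.track_format,
                               name=f"condition.{cond}")
        matrices = {cond: mg.signal_matrix(tr, genes, config.window,
                                           config.bin_size)
                    for cond, tr in cond_tracks.items()}
        for cond, m in matrices.items():
            mg.export_matrix(m, os.path.join(matrix_dir, f"{cond}.matrix.tsv"))
            profile, ncontrib = mg.anchor_profile(m)
            mg.export_profile(profile, ncontrib, m.bin_offsets(),
                              os.path.join(matrix_dir, f"{cond}.profile.tsv"))
        if order_ref is not None:
            ref = matrices[order_ref]
            ordered = {cond: mg.order_rows(m, ref) for cond, m in matrices.items()}
            for cond, m in ordered.items():
                mg.export_matrix(m, os.path.join(matrix_dir,
                                                 f"{cond}.ordered.tsv"))
            for i, a in enumerate(conditions):
                for b in conditions[i + 1:]:
                    diff = mg.difference_matrix(ordered[a], ordered[b])
                    mg.export_matrix(diff, os.path.join(
                        matrix_dir, f"diff.{a}_minus_{b}.tsv"))

    # --- manifest ------------------------------------------------------------
    artifacts = {}
    for root, _dirs, files in os.walk(out):
        for fname in sorted(files):
            if fname == "manifest.json" or fname.endswith(".failed"):
                continue
            full = os.path.join(root, fname)
            artifacts[os.path.relpath(full, out)] = _sha256(full)
    manifest = {
        "parameters": config.params_dict(),
        "samples": [dataclasses.asdict(r) for r in config.samples],
        "conditions": conditions,
        "library_counts": {name: {"n_spike": c.n_spike, "n_exp": c.n_exp}
                           for name, c in lib_counts.items()},
        "factors": {name: {"p_input": f.p_input, "p_ip": f.p_ip,
                           "factor": f.factor}
                    for name, f in factors.items()},
        "artifacts": artifacts,
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
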