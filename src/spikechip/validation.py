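"""Self-validation on the simulated study design.

Runs the complete pipeline on a simulated spike-in experiment — a
wild-type IP, two reduced-efficiency mutant IPs (50% and 20%), and an
input library, all with 10% spike-in chromatin — and scores how well each
stage recovers the known ground truth: demultiplexing fidelity, alignment
fidelity, the input spike fraction, and above all whether the
spike-calibrated tracks recover the programmed mutant/wild-type
efficiency ratios that plain SPMR scaling hides.
"""

from __future__ import annotations

import json
import os

import numpy as np
from scipy import stats as sps

from . import io as sio
from . import metagene as mg
from . import pileup as pl
from . import simulate as sim
from .io import EXPERIMENTAL, SPIKE
from .pipeline import run_pipeline, validate_config

# pairwise Hamming distance 6; safe for one-mismatch demultiplexing
BARCODES = {"input": "AACCGG", "WT": "CCGGTT", "mut50": "GGTTAA", "mut20": "TTAACC"}
EFFICIENCIES = {"WT": 1.0, "mut50": 0.5, "mut20": 0.2}


def default_experiment_config(outdir: str, seed: int,
                              reads_per_sample: int | None = None,
                              design: dict | None = None) -> dict:
    """The standard validation experiment as a pipeline configuration."""
    samples = [{"name": "input1", "barcode": BARCODES["input"], "kind": "input",
                "condition": "none"}]
    for cond, eff in EFFICIENCIES.items():
        samples.append({"name": f"{cond}_IP", "barcode": BARCODES[cond],
                        "kind": "IP", "condition": cond, "efficiency": eff,
                        "input_sample": "input1"})
    if reads_per_sample is not None:
        for row in samples:
            row["n_reads"] = reads_per_sample
    return {"outdir": outdir, "seed": seed, "simulate": dict(design or {}),
            "samples": samples, "params": {"order_by": "WT"}}


def _oriented_masks(truth: dict, lengths: dict[str, int]
                    ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Boolean masks of gene windows ([TSS, TSS+1500) into the gene body)
    and of pure-background bases (outside every enrichment span)."""
    window = mg.DEFAULT_WINDOW
    span = sim.ENRICHMENT_SPAN_DECAYS * truth["config"]["decay_length"]
    gene_mask = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}
    enriched = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}
    for g in truth["genes"]:
        c, tss = g["chrom"], g["tss"]
        n = lengths[c]
        if g["strand"] == "+":
            gene_mask[c][tss:min(tss + window, n)] = True
            enriched[c][tss:min(tss + span, n)] = True
        else:
            gene_mask[c][max(tss - window + 1, 0):tss + 1] = True
            enriched[c][max(tss - span + 1, 0):tss + 1] = True
    background = {c: ~enriched[c] for c in enriched}
    return gene_mask, background


def _masked_mean(track: pl.CoverageTrack, mask: dict[str, np.ndarray]) -> float:
    total = sum(float(track.values[c][m].sum()) for c, m in mask.items())
    n = sum(int(m.sum()) for m in mask.values())
    return total / n


def _signal(track: pl.CoverageTrack, gene_mask, background) -> float:
    """Background-subtracted mean signal over gene windows."""
    return _masked_mean(track, gene_mask) - _masked_mean(track, background)


def _demux_fidelity(outdir: str, samples: list[str]) -> tuple[float, float]:
    """(assignment rate, correct-assignment rate among assigned reads)."""
    total = assigned = correct = 0
    for name in samples:
        for rid, _seq, _q in sio.iter_fastq(os.path.join(outdir, "demux",
                                                         f"{name}.fastq")):
            assigned += 1
            if sim.parse_read_id(rid)["sample"] == name:
                correct += 1
    total = assigned
    for rid, _seq, _q in sio.iter_fastq(os.path.join(outdir, "demux",
                                                     "unassigned.fastq")):
        total += 1
    return assigned / total, correct / assigned


def _alignment_fidelity(outdir: str, samples: list[str]) -> float:
    """Fraction of assigned reads placed on their true genome and locus.

    The aligner trims the first (5'-most) base, which shifts the leftmost
    coordinate of plus-strand reads by one.
    """
    n = correct = 0
    for name in samples:
        for label in (EXPERIMENTAL, SPIKE):
            path = os.path.join(outdir, "align", f"{name}.{label}.bed")
            for chrom, start, _end, rid, _s, strand in sio.read_bed6(path):
                n += 1
                t = sim.parse_read_id(rid)
                want_start = t["leftmost"] + (1 if t["strand"] == "+" else 0)
                if (t["genome"] == label and t["chrom"] == chrom
                        and t["strand"] == strand and want_start == start):
                    correct += 1
    return correct / n


def run_validation(outdir: str, seed: int, reads_per_sample: int | None = None,
                   design: dict | None = None) -> dict:
    """Run the standard experiment and score every stage against truth."""
    cfg = validate_config(default_experiment_config(outdir, seed,
                                                    reads_per_sample, design))
    manifest = run_pipeline(cfg)

    with open(os.path.join(outdir, "sim", "truth.json")) as fh:
        truth = json.load(fh)
    lengths = truth["genome_lengths"][EXPERIMENTAL]
    gene_mask, background = _oriented_masks(truth, lengths)

    def load(name: str, stage: str) -> pl.CoverageTrack:
        return pl.read_track(os.path.join(outdir, "tracks",
                                          f"{name}.{stage}.bedgraph"), lengths)

    cal_signal = {c: _signal(load(f"condition.{c}", "calibrated"),
                             gene_mask, background) for c in EFFICIENCIES}
    spmr_signal = {c: _signal(load(f"{c}_IP", "spmr"), gene_mask, background)
                   for c in EFFICIENCIES}

    counts = manifest["library_counts"]
    p_input = counts["input1"]["n_spike"] / (counts["input1"]["n_spike"]
                                             + counts["input1"]["n_exp"])
    sample_names = list(BARCODES)
    sample_names = ["input1"] + [f"{c}_IP" for c in EFFICIENCIES]
    assign_rate, demux_correct = _demux_fidelity(outdir, sample_names)
    locus_rate = _alignment_fidelity(outdir, sample_names)

    wt_matrix = mg.read_matrix(os.path.join(outdir, "matrix", "WT.matrix.tsv"))
    profile, _counts = mg.anchor_profile(wt_matrix)
    anchor_rho = float(sps.spearmanr(np.arange(profile.size), profile).statistic)
    true_amp = {g["id"]: g["amplitude"] for g in truth["genes"]}
    amps = np.array([true_amp[g] for g in wt_matrix.gene_ids])
    row_rho = float(sps.spearmanr(wt_matrix.row_means(), amps).statistic)

    return {
        "manifest": manifest,
        "truth": truth,
        "outdir": outdir,
        "p_input": p_input,
        "factors": manifest["factors"],
        "calibrated_ratio": {c: cal_signal[c] / cal_signal["WT"]
                             for c in ("mut50", "mut20")},
        "spmr_ratio": {c: spmr_signal[c] / spmr_signal["WT"]
                       for c in ("mut50", "mut20")},
        "true_efficiency": dict(EFFICIENCIES),
        "demux_assignment_rate": assign_rate,
        "demux_correct_rate": demux_correct,
        "alignment_true_locus_rate": locus_rate,
        "anchor_profile_spearman": anchor_rho,
        "row_order_spearman": row_rho,
        "reads_per_sample": reads_per_sample
            or sim.SimConfig(**(design or {})).n_ip_reads,
    }
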