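"""TSS-anchored signal matrices, heatmap orderings and anchor profiles.

A signal matrix holds, for each gene, the binned mean track signal over a
window (default 1500 bp) running from the TSS into the gene body,
strand-oriented so bin 0 always abuts the TSS.  Rows whose window falls
off the chromosome are kept as missing (NaN) rows so gene sets stay
aligned across samples.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (ConfigError, EmptyMatrixError, IncompatibilityError,
                     ProvenanceError)
from .pileup import SPIKE_CALIBRATED, SPMR, CoverageTrack
from .simulate import GeneAnnotation

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1500
DEFAULT_BIN_SIZE = 25


@dataclass
class SignalMatrix:
    """Genes x bins matrix of binned track signal anchored at the TSS."""

    gene_ids: list[str]
    bin_size: int
    window: int
    values: np.ndarray  # rows x n_bins, NaN for missing rows
    source: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.window // self.bin_size

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), self.n_bins):
            raise IncompatibilityError(
                f"values shape {self.values.shape} != "
                f"({len(self.gene_ids)}, {self.n_bins})")

    def bin_offsets(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_size

    def row_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=1)

    def missing_rows(self) -> np.ndarray:
        return np.isnan(self.values).all(axis=1)


def signal_matrix(track: CoverageTrack, genes: list[GeneAnnotation],
                  window: int = DEFAULT_WINDOW,
                  bin_size: int = DEFAULT_BIN_SIZE) -> SignalMatrix:
    """Bin the track over [TSS, TSS+window) oriented into each gene body.

    Bin j of a "+" gene is the mean over [tss + j*b, tss + (j+1)*b); of a
    "-" gene the mean over [tss - (j+1)*b + 1, tss - j*b + 1).
    """
    if track.provenance not in (SPMR, SPIKE_CALIBRATED):
        raise ProvenanceError(
            f"signal matrices require SPMR or spike-calibrated tracks, "
            f"got {track.provenance!r}")
    if window % bin_size != 0:
        raise ConfigError(f"window {window} not divisible by bin_size {bin_size}")
    n_bins = window // bin_size
    rows = np.full((len(genes), n_bins), np.nan)
    n_missing = 0
    for i, gene in enumerate(genes):
        vals = track.values.get(gene.chrom)
        if vals is None:
            n_missing += 1
            continue
        if gene.strand == "+":
            lo, hi = gene.tss, gene.tss + window
            if lo < 0 or hi > vals.size:
                n_missing += 1
                continue
            win = vals[lo:hi]
        else:
            lo, hi = gene.tss - window + 1, gene.tss + 1
            if lo < 0 or hi > vals.size:
                n_missing += 1
                continue
            win = vals[lo:hi][::-1]
        rows[i] = win.reshape(n_bins, bin_size).mean(axis=1)
    if n_missing:
        logger.warning("%d/%d genes had out-of-bounds windows and were kept "
                       "as missing rows", n_missing, len(genes))
    return SignalMatrix([g.id for g in genes], bin_size, window, rows,
                        source={"provenance": track.provenance,
                                "reads_used": track.reads_used})


def order_rows(matrix: SignalMatrix, reference: SignalMatrix) -> SignalMatrix:
    """Sort rows by descending row mean of ``reference`` (ties by gene id);
    missing reference rows sink to the bottom."""
    if set(matrix.gene_ids) != set(reference.gene_ids):
        raise IncompatibilityError("matrices cover different gene sets")
    ref_means = dict(zip(reference.gene_ids, reference.row_means()))
    def sort_key(gid: str):
        m = ref_means[gid]
        return (-m if np.isfinite(m) else np.inf, gid)
    order = sorted(matrix.gene_ids, key=sort_key)
    idx = [matrix.gene_ids.index(g) for g in order]
    return SignalMatrix(order, matrix.bin_size, matrix.window,
                        matrix.values[idx],
                        source={**matrix.source, "ordered_by": reference.source})


def anchor_profile(matrix: SignalMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean over non-missing rows plus per-bin contributing counts."""
    finite = np.isfinite(matrix.values)
    counts = finite.sum(axis=0)
    if not finite.any():
        raise EmptyMatrixError("all rows are missing")
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(matrix.values, axis=0)
    return profile, counts


def difference_matrix(a: SignalMatrix, b: SignalMatrix) -> SignalMatrix:
    """Elementwise a - b for identically ordered, identically binned matrices."""
    if a.gene_ids != b.gene_ids:
        raise IncompatibilityError("gene sets or row orders differ")
    if (a.bin_size, a.window) != (b.bin_size, b.window):
        raise IncompatibilityError("bin geometry differs")
    return SignalMatrix(list(a.gene_ids), a.bin_size, a.window,
                        a.values - b.values,
                        source={"a": a.source, "b": b.source, "op": "difference"})


def export_matrix(matrix: SignalMatrix, path: str | os.PathLike) -> None:
    """TSV with a header row of bin start offsets and gene ids in column 1."""
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids,
                      columns=matrix.bin_offsets())
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")


def read_matrix(path: str | os.PathLike) -> SignalMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    offsets = df.columns.astype(int).to_numpy()
    if offsets.size > 1:
        bin_size = int(offsets[1] - offsets[0])
    else:
        bin_size = int(offsets[0]) if offsets[0] else 1
    window = bin_size * offsets.size
    return SignalMatrix(list(df.index), bin_size, window, df.to_numpy())


def export_profile(profile: np.ndarray, counts: np.ndarray,
                   offsets: np.ndarray, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tmean_signal\tn_genes\n")
        for off, v, n in zip(offsets, profile, counts):
            fh.write(f"{off}\t{v:.6g}\t{n}\n")
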