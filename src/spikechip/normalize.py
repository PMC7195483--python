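"""Spike-in normalization factors.

The factor for an IP library is

    factor = p_input / sqrt(p_ip)

where p_input and p_ip are the proportions of reads exclusively assigned
to the spike genome in the matched input library and in the IP library.
The square root compensates for the per-library SPMR scaling already
applied to pileup tracks; the formula is implemented as stated, without
re-derivation.  Proportions are computed from exclusive assignment counts
taken before duplicate removal.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable

from .align import LibraryCounts
from .errors import DegenerateLibraryError
from .pileup import SPMR, SPIKE_CALIBRATED, CoverageTrack


@dataclass(frozen=True)
class NormFactor:
    sample: str
    p_input: float
    p_ip: float
    factor: float

    def __post_init__(self):
        if not (0 < self.p_input < 1):
            raise DegenerateLibraryError(
                f"p_input = {self.p_input} outside (0, 1) for {self.sample!r}")
        if not (0 < self.p_ip < 1):
            raise DegenerateLibraryError(
                f"p_ip = {self.p_ip} outside (0, 1) for {self.sample!r}")
        if not math.isclose(self.factor, self.p_input / math.sqrt(self.p_ip),
                            rel_tol=0, abs_tol=0):
            raise DegenerateLibraryError("factor != p_input / sqrt(p_ip)")


def spike_proportion(counts: LibraryCounts) -> float:
    """Spike reads over total exclusively assigned reads."""
    total = counts.n_spike + counts.n_exp
    if total <= 0:
        raise DegenerateLibraryError(f"library {counts.sample!r} has zero reads")
    return counts.n_spike / total


def norm_factor(input_counts: LibraryCounts, ip_counts: LibraryCounts) -> NormFactor:
    p_input = spike_proportion(input_counts)
    p_ip = spike_proportion(ip_counts)
    if p_ip == 0:
        raise DegenerateLibraryError(
            f"IP library {ip_counts.sample!r} has no spike reads: "
            "cannot divide by sqrt(0)")
    if not (0 < p_input < 1) or not (0 < p_ip < 1):
        raise DegenerateLibraryError(
            f"degenerate spike proportions (input={p_input}, "
            f"ip={p_ip} for {ip_counts.sample!r}); both must lie in (0, 1)")
    return NormFactor(sample=ip_counts.sample, p_input=p_input, p_ip=p_ip,
                      factor=p_input / math.sqrt(p_ip))


def apply_factor(track: CoverageTrack, f: NormFactor) -> CoverageTrack:
    """Scale an SPMR track by the spike-in factor (returns a new track)."""
    if track.provenance != SPMR:
        from .errors import ProvenanceError
        raise ProvenanceError(
            f"spike calibration requires an SPMR track, got {track.provenance!r}")
    return CoverageTrack(
        genome_label=track.genome_label,
        values={c: v * f.factor for c, v in track.values.items()},
        provenance=SPIKE_CALIBRATED, reads_used=track.reads_used)


def write_factor_report(rows: Iterable[tuple[LibraryCounts, LibraryCounts, NormFactor]],
                        path: str | os.PathLike) -> None:
    """TSV audit of every quantity entering each factor."""
    with open(path, "w") as fh:
        fh.write("sample\tn_spike_in\tn_exp_in\tn_spike_ip\tn_exp_ip\t"
                 "p_input\tp_ip\tfactor\n")
        for input_counts, ip_counts, f in rows:
            fh.write(f"{f.sample}\t{input_counts.n_spike}\t{input_counts.n_exp}\t"
                     f"{ip_counts.n_spike}\t{ip_counts.n_exp}\t"
                     f"{f.p_input:.6g}\t{f.p_ip:.6g}\t{f.factor:.6g}\n")


def read_factor_report(path: str | os.PathLike) -> dict[str, NormFactor]:
    factors = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("sample\t")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            sample, p_input, p_ip = parts[0], float(parts[5]), float(parts[6])
            # recompute so the exact factor invariant survives 6-digit printing
            factors[sample] = NormFactor(sample, p_input, p_ip,
                                         p_input / math.sqrt(p_ip))
    return factors
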