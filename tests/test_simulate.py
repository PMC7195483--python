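"""Unit and property tests of the synthetic-experiment generator."""

import dataclasses
import math

import numpy as np
import pytest

from spikechip import simulate as sim
from spikechip.errors import (ConfigError, DegenerateProfileError,
                              PlacementError)
from spikechip.io import EXPERIMENTAL, SPIKE

from conftest import small_config


class TestMakeGenomes:
    def test_deterministic_under_fixed_seed(self):
        cfg = small_config(seed=1)
        a = sim.make_genomes(cfg)
        b = sim.make_genomes(cfg)
        assert a[0].chroms == b[0].chroms
        assert a[1].chroms == b[1].chroms

    def test_seed_sensitivity(self):
        a, _ = sim.make_genomes(small_config(seed=1))
        b, _ = sim.make_genomes(small_config(seed=2))
        assert a.chroms != b.chroms

    def test_distinct_streams_for_the_two_genomes(self):
        exp, spike = sim.make_genomes(small_config(seed=1))
        assert exp.label == EXPERIMENTAL and spike.label == SPIKE
        first_exp = next(iter(exp.chroms.values()))
        first_spike = next(iter(spike.chroms.values()))
        assert first_exp[:1000] != first_spike[:1000]

    def test_genome_shorter_than_read_is_rejected(self):
        with pytest.raises(ConfigError):
            sim.make_genomes(small_config(exp_genome_length=40, n_chroms_exp=1))

    def test_requested_sizes(self):
        cfg = small_config()
        exp, spike = sim.make_genomes(cfg)
        assert exp.total_length == cfg.exp_genome_length
        assert spike.total_length == cfg.spike_genome_length
        assert len(exp.chroms) == cfg.n_chroms_exp


class TestMakeGeneset:
    def test_spacing_clearance_and_determinism(self, tiny_design):
        cfg, exp, _spike, genes = tiny_design
        assert len(genes) == cfg.n_genes
        by_chrom: dict[str, list[int]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.tss)
            length = len(exp.chroms[g.chrom])
            if g.strand == "+":
                assert g.tss + 1500 <= length
            else:
                assert g.tss - 1499 >= 0
        for positions in by_chrom.values():
            positions.sort()
            assert all(b - a >= cfg.min_gene_spacing
                       for a, b in zip(positions, positions[1:]))
        again = sim.make_geneset(exp, cfg.n_genes, cfg.min_gene_spacing,
                                 cfg.seed, peak_amplitude=cfg.peak_amplitude,
                                 amplitude_sigma=cfg.amplitude_sigma)
        assert again == genes

    def test_infeasible_placement_raises(self, tiny_design):
        _cfg, exp, _spike, _genes = tiny_design
        with pytest.raises(PlacementError):
            sim.make_geneset(exp, 1000, 5_000, seed=1)


class TestEnrichmentWeight:
    @pytest.mark.parametrize("d, efficiency, expected", [
        (0, 1.0, 10.0),                          # exp(0) = 1
        (500, 1.0, 1 + 9 * math.exp(-1)),        # one decay length: ~4.3106
        (0, 0.2, 2.8),                           # reduced-efficiency mutant
        (1500, 1.0, 1.0),                        # beyond 3 decay lengths
    ])
    def test_formula(self, d, efficiency, expected):
        cfg = small_config(peak_amplitude=9.0, decay_length=500,
                           background_rate=1.0, amplitude_sigma=0.0)
        gene = sim.GeneAnnotation("g1", "chrE1", 5000, "+", amplitude=9.0)
        w = sim.enrichment_weight(5000 + d, "chrE1", [gene], cfg,
                                  efficiency=efficiency)
        assert w == pytest.approx(expected, rel=1e-12)

    def test_minus_strand_orientation(self):
        cfg = small_config(peak_amplitude=9.0, decay_length=500,
                           background_rate=1.0)
        gene = sim.GeneAnnotation("g1", "chrE1", 5000, "-", amplitude=9.0)
        assert sim.enrichment_weight(5000, "chrE1", [gene], cfg,
                                     efficiency=1.0) == pytest.approx(10.0)
        assert sim.enrichment_weight(4500, "chrE1", [gene], cfg,
                                     efficiency=1.0) == pytest.approx(
            1 + 9 * math.exp(-1))
        # downstream of a minus gene means lower coordinates; above TSS is background
        assert sim.enrichment_weight(5100, "chrE1", [gene], cfg,
                                     efficiency=1.0) == 1.0

    def test_track_matches_scalar(self, tiny_design):
        cfg, exp, _spike, genes = tiny_design
        tracks = sim.enrichment_track(exp, genes, cfg, efficiency=0.7)
        rng = np.random.default_rng(0)
        chrom = genes[0].chrom
        for pos in rng.integers(0, len(exp.chroms[chrom]), size=50):
            assert tracks[chrom][pos] == pytest.approx(
                sim.enrichment_weight(int(pos), chrom, genes, cfg,
                                      efficiency=0.7), rel=1e-12)

    def test_band_means_strictly_decreasing(self, tiny_design):
        cfg, exp, _spike, genes = tiny_design
        tracks = sim.enrichment_track(exp, genes, cfg, efficiency=1.0)
        d = cfg.decay_length
        bands = []
        for band in range(sim.ENRICHMENT_SPAN_DECAYS):
            vals = []
            for g in genes:
                sign = 1 if g.strand == "+" else -1
                pos = g.tss + sign * np.arange(band * d, (band + 1) * d)
                vals.append(tracks[g.chrom][pos].mean())
            bands.append(np.mean(vals))
        assert bands[0] > bands[1] > bands[2]


class TestSimulateSample:
    def test_input_spike_fraction_binomial(self, tiny_design):
        cfg, exp, spike, genes = tiny_design
        cfg = cfg.replace(n_input_reads=100_000)
        reads, truth = sim.simulate_sample(cfg, (exp, spike), genes, "input",
                                           sample_name="in1")
        frac = np.mean([sim.parse_read_id(r[0])["genome"] == SPIKE
                        for r in reads])
        sigma = math.sqrt(0.1 * 0.9 / 100_000)
        assert truth.p_spike_expected == cfg.spike_mass_fraction
        assert abs(frac - 0.1) < 4 * sigma

    def test_read_sequences_match_their_recorded_origin(self, tiny_design):
        cfg, exp, spike, genes = tiny_design
        reads, _ = sim.simulate_sample(cfg, (exp, spike), genes, "IP",
                                       sample_name="WT")
        chroms = {**exp.chroms, **spike.chroms}
        blen = len(cfg.barcode)
        seen = {"+": 0, "-": 0}
        for rid, seq, qual in reads[:2000]:
            t = sim.parse_read_id(rid)
            assert seq[:blen] == cfg.barcode
            body = seq[blen:]
            ref = chroms[t["chrom"]][t["leftmost"]:t["leftmost"] + cfg.read_length]
            if t["strand"] == "-":
                ref = sim.reverse_complement(ref)
            assert body == ref
            assert qual == "I" * len(seq)
            seen[t["strand"]] += 1
        assert seen["+"] > 0 and seen["-"] > 0

    def test_efficiency_ordering_matches_closed_form(self, tiny_design):
        cfg, exp, spike, genes = tiny_design

        def closed_form_mean(efficiency):
            total = cfg.background_rate * exp.total_length
            span = sim.ENRICHMENT_SPAN_DECAYS * cfg.decay_length
            for g in genes:
                length = len(exp.chroms[g.chrom])
                n = min(span, length - g.tss) if g.strand == "+" else \
                    min(span, g.tss + 1)
                d = np.arange(n)
                total += efficiency * g.amplitude * np.exp(
                    -d / cfg.decay_length).sum()
            return total / exp.total_length

        truths = {}
        for eff in (1.0, 0.2):
            _, truth = sim.simulate_sample(
                cfg.replace(efficiency=eff), (exp, spike), genes, "IP",
                sample_name=f"e{eff}")
            truths[eff] = truth
            assert truth.mean_weight_exp == pytest.approx(
                closed_form_mean(eff), rel=1e-9)
        ratio = truths[0.2].mean_weight_exp / truths[1.0].mean_weight_exp
        assert ratio == pytest.approx(closed_form_mean(0.2) / closed_form_mean(1.0))

    def test_spike_yield_shifts_only_through_renormalization(self, tiny_design):
        cfg, exp, spike, genes = tiny_design
        truths = {}
        for eff in (1.0, 0.2):
            _, truths[eff] = sim.simulate_sample(
                cfg.replace(efficiency=eff), (exp, spike), genes, "IP",
                sample_name="same-name")
        # the spike profile itself is efficiency-independent ...
        assert truths[0.2].mean_weight_spike == truths[1.0].mean_weight_spike
        # ... so the spike fraction rises in the mutant only because the
        # experimental pull-down mass shrinks in the renormalization
        assert truths[0.2].p_spike_expected > truths[1.0].p_spike_expected
        s = cfg.spike_mass_fraction
        for t in truths.values():
            expect = (s * t.mean_weight_spike) / (
                s * t.mean_weight_spike + (1 - s) * t.mean_weight_exp)
            assert t.p_spike_expected == pytest.approx(expect, rel=1e-12)

    def test_degenerate_profile_raises(self, tiny_design):
        cfg, exp, spike, _genes = tiny_design
        cfg = cfg.replace(background_rate=0.0)
        with pytest.raises(DegenerateProfileError):
            sim.simulate_sample(cfg, (exp, spike), [], "IP")

    def test_truth_record_roundtrip(self, tiny_design):
        cfg, exp, spike, genes = tiny_design
        _, truth = sim.simulate_sample(cfg, (exp, spike), genes, "IP",
                                       sample_name="WT")
        assert sim.TruthRecord.from_dict(truth.to_dict()) == truth


@pytest.fixture(scope="module")
def experiment(tmp_path_factory):
    cfg = small_config(n_ip_reads=2000, n_input_reads=2000)
    samples = [
        sim.SampleSpec("in1", "input", cfg.replace(barcode="AACCGG")),
        sim.SampleSpec("WT", "IP", cfg.replace(barcode="CCGGTT")),
        sim.SampleSpec("mut", "IP",
                       cfg.replace(barcode="GGTTAA", efficiency=0.2)),
    ]
    out = tmp_path_factory.mktemp("exp")
    return samples, out, sim.simulate_experiment(samples, out)


class TestSimulateExperiment:
    def test_outputs_and_truth(self, experiment):
        samples, _out, paths = experiment
        import json
        with open(paths["truth"]) as fh:
            truth = json.load(fh)
        assert sorted(truth["samples"]) == ["WT", "in1", "mut"]
        assert truth["samples"]["mut"]["efficiency"] == 0.2
        n = sum(1 for _ in open(paths["fastq"])) // 4
        assert n == 6000

    def test_byte_identical_rerun(self, experiment, tmp_path):
        samples, _out, paths = experiment
        paths2 = sim.simulate_experiment(samples, tmp_path)
        for key in ("fastq", "exp_genome", "genes", "truth"):
            assert open(paths[key]).read() == open(paths2[key]).read()

    def test_duplicate_barcode_rejected(self, experiment):
        samples, _, _ = experiment
        dup = [samples[0],
               dataclasses.replace(samples[1],
                                   config=samples[1].config.replace(
                                       barcode=samples[0].config.barcode))]
        with pytest.raises(ConfigError):
            sim.simulate_experiment(dup, "unused")

    def test_mismatched_design_rejected(self, experiment):
        samples, _, _ = experiment
        bad = [samples[0], dataclasses.replace(
            samples[1], config=samples[1].config.replace(n_genes=99))]
        with pytest.raises(ConfigError):
            sim.simulate_experiment(bad, "unused")
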