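import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spikechip import simulate as sim

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def small_config(**overrides) -> sim.SimConfig:
    """A desk-scale variant of the experiment design for fast unit tests."""
    base = dict(exp_genome_length=150_000, spike_genome_length=30_000,
                n_chroms_exp=2, n_chroms_spike=1, n_genes=10,
                min_gene_spacing=6_000, n_ip_reads=20_000,
                n_input_reads=20_000, seed=3)
    base.update(overrides)
    return sim.SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_design():
    cfg = small_config()
    exp, spike = sim.make_genomes(cfg)
    genes = sim.make_geneset(exp, cfg.n_genes, cfg.min_gene_spacing, cfg.seed,
                             peak_amplitude=cfg.peak_amplitude,
                             amplitude_sigma=cfg.amplitude_sigma)
    return cfg, exp, spike, genes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
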