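import numpy as np
import pytest

from triohet.pileup import SNPFilters, build_pileup, call_snps
from triohet.simulate import (SimConfig, simulate_reads, simulate_reference,
                              simulate_trio_genotypes)


@pytest.fixture(scope="session")
def small_sim():
    """A small clean (error-free) trio dataset with truth."""
    cfg = SimConfig(n_transcripts=30, length_range=(400, 400),
                    snp_sites_total=100, coverage_per_variety=30,
                    read_len=50, error_rate=0.0, ssr_per_transcript_prob=0.4,
                    seed=7)
    reference, truth_ssrs = simulate_reference(cfg)
    truth_sites = simulate_trio_genotypes(cfg, reference)
    return cfg, reference, truth_ssrs, truth_sites


@pytest.fixture(scope="session")
def small_sim_called(small_sim):
    """The small dataset piled up and called with default filters."""
    cfg, reference, _, truth_sites = small_sim
    pile = build_pileup(simulate_reads(cfg, reference, truth_sites),
                        reference, cfg.varieties)
    sites = call_snps(pile, SNPFilters())
    return cfg, reference, truth_sites, pile, sites


@pytest.fixture
def rng():
    return np.random.default_rng(42)
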