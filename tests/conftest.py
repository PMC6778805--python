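import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gbsparent import call_genotypes, estimate_allele_freqs
from gbsparent.simulate import SimConfig, simulate_dataset, simulate_pedigree_genotypes, simulate_reads


@pytest.fixture(scope="session")
def herd():
    """A mid-size herd under binomial reads: counts, candidates, truth."""
    config = SimConfig(n_snps=2000, n_sires=10, n_dams=40, n_offspring=60, depth_mean=2.0, seed=2024)
    counts, candidates, truth = simulate_dataset(config)
    return config, counts, candidates, truth


@pytest.fixture(scope="session")
def herd_calls(herd):
    _, counts, _, _ = herd
    return call_genotypes(counts)


@pytest.fixture(scope="session")
def trio_panel():
    """Independent true trios at 10,000 SNPs, depth ~ Poisson(3), binomial
    reads, with the founder frequencies kept (the theory assumes p known)."""
    config = SimConfig(n_snps=10000, n_sires=120, n_dams=120, n_offspring=30, depth_mean=3.0, seed=77)
    true_g = simulate_pedigree_genotypes(config)
    counts = simulate_reads(true_g, config)
    return config, true_g, counts
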