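import numpy as np
import pandas as pd
import pytest

from crossfdr import LdGraph, SimConfig, simulate_panel
from crossfdr.sumstats import harmonize


@pytest.fixture(scope="session")
def null_panel():
    """All-null panel, no LD."""
    return simulate_panel(SimConfig(n_snps=10_000, seed=11))


@pytest.fixture(scope="session")
def shared_panel():
    """Panel with genuine cross-trait overlap and block LD."""
    cfg = SimConfig(n_snps=20_000, frac_shared=0.01, frac_spec1=0.005,
                    frac_spec2=0.005, effect_sd1=4.0, effect_sd2=4.0,
                    ld_block_size=5, within_block_r2=0.4, seed=5)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def shared_pairs(shared_panel):
    return harmonize(shared_panel.sumstats1, shared_panel.sumstats2)


@pytest.fixture()
def toy_graph():
    """Five SNPs: a-b-c chained above threshold, d weakly linked, e isolated."""
    g = LdGraph()
    g.add_pair("a", "b", 0.5)
    g.add_pair("b", "c", 0.3)
    g.add_pair("c", "d", 0.05)
    return g


@pytest.fixture()
def toy_results():
    rng = np.random.default_rng(0)
    n = 6
    return pd.DataFrame({
        "snp_id": list("abcdef"),
        "chrom": ["1"] * 3 + ["2"] * 3,
        "pos": [100, 200, 300, 100, 200, 300],
        "p1": [1e-6, 1e-4, 0.5, 1e-5, 0.2, 0.9],
        "p2": [1e-5, 1e-3, 0.4, 1e-6, 0.3, 0.8],
        "z1": [4.9, 3.9, -0.7, 4.4, 1.3, 0.1],
        "z2": [-4.4, 3.3, 0.8, 4.9, -1.0, 0.3],
        "condfdr_1given2": [0.001, 0.009, 0.8, 0.002, 0.5, 0.99],
        "condfdr_2given1": [0.004, 0.02, 0.7, 0.001, 0.6, 0.95],
        "conjfdr": [0.004, 0.02, 0.8, 0.002, 0.6, 0.99],
    })
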