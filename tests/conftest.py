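"""Shared fixtures: small seeded simulations reused across test modules."""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from triomap import SimConfig, simulate_trio_dataset


@pytest.fixture(scope="session")
def recessive_sim():
    """Consanguineous trio, implanted recessive causal allele, 60 controls,
    14,500 sites - the workhorse dataset for QC/ROH/filter tests."""
    cfg = SimConfig(seed=20240901, n_controls=60, n_sites_per_chrom=500)
    return simulate_trio_dataset(cfg)


@pytest.fixture(scope="session")
def outbred_sim():
    """Outbred trio (parents unrelated): clean parent-offspring pairs for
    relatedness tests."""
    cfg = SimConfig(template="outbred", depth=3, seed=77, n_controls=60,
                    n_sites_per_chrom=500)
    return simulate_trio_dataset(cfg)
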