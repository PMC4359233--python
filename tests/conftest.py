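import numpy as np
import pandas as pd
import pytest

from polpoised.simulate import SimConfig, simulate_chipchip, simulate_expression


@pytest.fixture(scope="session")
def small_sim():
    """One small noisy dataset shared across tests (fixed seed)."""
    config = SimConfig(n_genes=100, seed=11)
    probes, truth = simulate_chipchip(config)
    lines, cohorts = simulate_expression(config, truth)
    return config, probes, truth, lines, cohorts


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_probe_table(gene_id, offsets, log_ratios):
    return pd.DataFrame(
        {
            "probe_id": [f"{gene_id}:{o}" for o in offsets],
            "gene_id": gene_id,
            "offset_nt": list(offsets),
            "log_ratio": list(log_ratios),
        }
    )


@pytest.fixture()
def probe_table_factory():
    return make_probe_table
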