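import numpy as np
import pandas as pd
import pytest

from rdcscan.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_bundle():
    """A 20-Mb synthetic genome with planted RDCs, shared across tests."""
    cfg = SimConfig(seed=11, chrom_length=20_000_000)
    return simulate_all(cfg)


@pytest.fixture()
def gene_frame():
    def make(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "rpkm"])

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
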