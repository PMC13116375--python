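import pytest
from hypothesis import settings

from panchrom3d import SimConfig, simulate_pan_dataset

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A 15-genome dataset small enough for per-module tests."""
    cfg = SimConfig(seed=7, chrom_sizes={"chr1": 30_000_000},
                    n_boundaries=30, n_loops=30, n_ltcres=50, n_svs=100,
                    n_gene_families=200)
    return simulate_pan_dataset(cfg)
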