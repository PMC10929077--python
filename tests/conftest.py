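import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by integration-style tests."""
    import methylqc as m

    cfg = m.simulate.SimConfig(n_sites=2000, seed=11)
    truth = m.simulate.simulate_methylome(cfg)
    reads = m.simulate.simulate_reads(truth, cfg)
    sites = m.pipeline.methylome_from_reads(reads, truth=truth)
    return cfg, truth, reads, sites


def make_calls_frame(rows):
    """Build a per-read calls frame from (strand, llr) tuples at one unit."""
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "strand": [s for s, _ in rows],
            "start": 100,
            "end": 101,
            "read_id": [f"r{i}" for i in range(len(rows))],
            "llr": [v for _, v in rows],
            "n_motifs": 1,
        }
    )
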