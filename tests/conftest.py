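import numpy as np
import pandas as pd
import pytest

from methcontext import GenomeSequence, MethylomeTable, SimConfig, simulate_genome
from methcontext.simulate import simulate_preference_profile


@pytest.fixture
def tiny_genome() -> GenomeSequence:
    # one CpG at 1-based positions 4-5 of c1; c2 is CpG-free
    return GenomeSequence({"c1": "TTACGGTT", "c2": "AAAATTTT"})


@pytest.fixture
def methylome_factory():
    def make(rows, sample_id="s"):
        df = pd.DataFrame(rows, columns=["contig", "pos", "strand", "n_meth", "n_unmeth"])
        return MethylomeTable(sample_id, df)

    return make


@pytest.fixture(scope="session")
def sim_bundle():
    """A small but context-complete simulated dataset shared by tests."""
    config = SimConfig(seed=11, genome_length=150_000, n_contigs=2,
                       cgi_count=30, cgi_length=600)
    genome, cgis = simulate_genome(config)
    profiles = {
        e: simulate_preference_profile(500 + i, name=e)
        for i, e in enumerate(sorted(config.enzyme_weights))
    }
    return {"config": config, "genome": genome, "cgis": cgis, "profiles": profiles}
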