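import numpy as np
import pandas as pd
import pytest

from orzone import sim


@pytest.fixture(scope="session")
def params():
    return sim.RheostatParams(seed=11)


@pytest.fixture(scope="session")
def genome(params):
    return sim.build_genome(params)


@pytest.fixture(scope="session")
def mosn_tissue(params):
    """Mature-neuron tissue shared across tests (read-only)."""
    return sim.simulate_tissue(params, 40, stage_mix={"mOSN": 1.0})


@pytest.fixture(scope="session")
def mixed_tissue(params):
    return sim.simulate_tissue(params, 60, stage_mix={"INP": 0.5, "mOSN": 0.5})


@pytest.fixture()
def toy_annotation():
    """Three hand-placed OR genes on two chromosomes."""
    return pd.DataFrame(
        {
            "gene_id": ["OrA", "OrB", "OrC"],
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [10_000, 30_000, 5_000],
            "end": [20_000, 45_000, 9_000],
            "strand": ["+", "-", "+"],
            "or_class": ["I", "II", "II"],
            "zonal_index": [1.0, 1.2, 4.9],
            "zone": [1, 1, 5],
            "cluster_id": ["c1", "c1", "c2"],
        }
    )


@pytest.fixture(scope="session")
def or_loci(genome):
    return [
        (g.gene_id, g.chrom, (g.start + g.end) // 2) for g in genome.itertuples()
    ]


@pytest.fixture(scope="session")
def zone_of(genome):
    return {
        g.gene_id: ("I" if g.or_class == "I" else int(g.zone))
        for g in genome.itertuples()
    }


def rng(*key):
    return np.random.default_rng(list(key))
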