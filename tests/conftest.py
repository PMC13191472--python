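import numpy as np
import pandas as pd
import pytest

from bivalency.genome_io import GeneModel, GenomicInterval, PeakSet
from bivalency.simulate import SimulationConfig, simulate_run
from bivalency.states import K4, K27, ChromatinState


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_genes():
    """Three single-TSS genes on two chromosomes, both strands."""
    return [
        GeneModel("gA", "chr1", "+", [10000]),
        GeneModel("gB", "chr1", "-", [50000]),
        GeneModel("gC", "chr2", "+", [10000]),
    ]


def make_peakset(sample_id, mark, triples, **kw):
    return PeakSet(
        sample_id=sample_id,
        mark=mark,
        intervals=[GenomicInterval(c, s, e) for c, s, e in triples],
        **kw,
    )


@pytest.fixture
def noise_free_run(tmp_path):
    """A small synthetic run with all noise channels off."""
    config = SimulationConfig(
        n_genes=120, n_chroms=2, n_samples=3, seed=7,
        dropout={K4: 0.0, K27: 0.0}, false_positive_rate=0.0,
    )
    return config, simulate_run(config, tmp_path / "run")


def random_state_series(rng, genes, prefix=""):
    states = list(ChromatinState)
    return pd.Series(
        [states[i] for i in rng.integers(0, 4, size=len(genes))],
        index=genes, dtype=object,
    )
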