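import numpy as np
import pandas as pd
import pytest

import rootmeth as rm


def make_track(rows, sample="S0", replicate="R1"):
    """Build a track from (chrom, pos, strand, context, mc, cov) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "mc", "cov"]
    )
    return rm.MethylomeTrack(sample=sample, replicate=replicate, sites=df)


def by_sample(tracks):
    groups = {}
    for t in tracks:
        groups.setdefault(t.sample, []).append(t)
    return groups


@pytest.fixture(scope="session")
def small_config():
    return rm.SimulationConfig(
        n_genes=20, n_tes=40, chrom_length=200_000, planted_dmr_count=20, seed=1
    )


@pytest.fixture(scope="session")
def small_fixture(small_config):
    """(annotation, tracks, matrix, truth) for a 200-kb two-stage genome."""
    return rm.simulate_all(small_config)


@pytest.fixture(scope="session")
def dmr_fixture():
    """The DMR-recovery fixture: 1 Mb, 200 planted hypo-CHH windows,
    delta 0.3 on a 0.05 baseline, 25x depth, two samples of two replicates."""
    config = rm.SimulationConfig(seed=11)
    annotation, tracks, matrix, truth = rm.simulate_all(config)
    return config, annotation, tracks, truth


@pytest.fixture(scope="session")
def corr_config():
    return rm.SimulationConfig(
        n_genes=60,
        n_tes=150,
        short_te_fraction=0.8,
        chrom_length=500_000,
        planted_dmr_count=120,
        n_samples=9,
        correlated_gene_fraction=0.4,
        seed=3,
    )


@pytest.fixture(scope="session")
def corr_fixture(corr_config):
    """Nine-stage fixture with planted methylation-expression links."""
    return rm.simulate_all(corr_config)
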