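import numpy as np
import pytest

from cre_enrich import simulate
from cre_enrich.intervals import GenomeLayout


@pytest.fixture(scope="session")
def small_sim_config():
    cfg = simulate.SimConfig(seed=7)
    cfg.genome.chrom_lengths = {"chr1": 300_000, "chr2": 200_000}
    cfg.genome.genes_per_mb = 20.0
    cfg.gwas.n_hits = 120
    cfg.gwas.n_significant = 80
    cfg.gwas.n_trait_loci = 3
    cfg.peaks.n_peaks = 200
    cfg.projections.n_dars = 400
    cfg.projections.n_target_dars = 800
    return cfg


@pytest.fixture(scope="session")
def small_genome(small_sim_config):
    layout, sequences, genes = simulate.simulate_genome(small_sim_config)
    return layout, sequences, genes


@pytest.fixture(scope="session")
def small_panel(small_sim_config):
    layout = GenomeLayout(small_sim_config.genome.chrom_lengths)
    return simulate.simulate_panel(small_sim_config, layout)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    """Uniformly random valid intervals for oracle comparisons."""
    import pandas as pd

    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, max_pos, size=n)
    length = rng.integers(1, max_len, size=n)
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})
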