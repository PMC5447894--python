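import numpy as np
import pytest

from genact.normalization import length_gc_offsets, offset_matrix, tmm_factors
from genact.simdata import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """1000-gene two-type dataset with inactive and DE genes; baseline is
    chosen so the per-sample renormalization is close to 1 (total rate ~
    library size), keeping the CPM scale interpretable."""
    cfg = SimConfig(
        n_genes=1000,
        frac_inactive=0.2,
        frac_de=0.1,
        lfc_magnitude=2.0,
        dispersion_mean=0.1,
        replicate_sd=0.1,
        baseline_mean=6.4,
        baseline_sd=1.0,
        inactive_leak_cpm=0.1,
        bias_length=0.4,
        bias_gc=0.2,
        seed=42,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    nf = tmm_factors(small_sim.counts)
    gene_off = length_gc_offsets(small_sim.counts, small_sim.features, nf)
    offsets = offset_matrix(small_sim.counts, nf, gene_off)
    return nf, gene_off, offsets


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
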