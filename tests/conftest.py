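import numpy as np
import pytest

from karyoscan import matrix as mx
from karyoscan.simulate import SimConfig, SimInversion, simulate_dataset


def make_matrix(G, chrom=None, pos=None, samples=None, **kw):
    """Small GenotypeMatrix from a dosage array (rows = samples)."""
    G = np.asarray(G, dtype=np.int8)
    n_samp, n_site = G.shape
    if chrom is None:
        chrom = ["chr1"] * n_site
    if pos is None:
        pos = np.arange(1, n_site + 1) * 100
    if samples is None:
        samples = [f"S{i:03d}" for i in range(n_samp)]
    return mx.from_arrays(samples=samples, chrom=chrom, pos=pos, G=G, **kw)


@pytest.fixture
def tiny_gm():
    """4 samples x 6 sites with one missing genotype."""
    G = np.array([
        [0, 1, 2, 0, 1, 2],
        [0, 0, 1, 1, 2, 2],
        [2, 1, 0, 2, 1, 0],
        [1, 1, 1, -1, 0, 2],
    ])
    return make_matrix(G)


@pytest.fixture(scope="session")
def inversion_scenario():
    """One 24-sample dataset with a single known inversion (q=0.5, d=0.9)."""
    cfg = SimConfig(
        n_samples=24,
        chromosomes=[("chr1", 5_000_000, 50_000), ("chr2", 5_000_000, 50_000)],
        inversions=[SimInversion("chr2", 2_000_001, 3_000_000,
                                 alt_arrangement_freq=0.5, divergence=0.9)],
        seed=7,
    )
    gm, truth = simulate_dataset(cfg)
    return cfg, gm, truth
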