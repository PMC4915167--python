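import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import bayesqtl as bq
from bayesqtl.synth import SimConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_animals=300, n_snps=1200, n_chromosomes=3, n_sires=20, seed=42
    )


@pytest.fixture(scope="session")
def small_genotypes(small_cfg):
    return bq.simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def warm_sampler():
    """Trigger the sampler's jit compilation once per session."""
    cfg = SimConfig(n_animals=40, n_snps=60, n_chromosomes=1, n_sires=5, seed=1)
    G = bq.simulate_genotypes(cfg)
    phen, _ = bq.simulate_traits(G, cfg)
    bq.fit_bayesc(G, phen, bq.ModelConfig(pi=0.05, n_iter=100, burn_in=20, seed=1))
    return True


def make_genotype_matrix(Z, chrom=None, pos=None):
    """Build a GenotypeMatrix from a raw array with an auto-generated map."""
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    mm = pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(m)], "chrom": chrom, "pos_bp": pos}
    )
    ids = np.array([f"a{i}" for i in range(n)])
    return bq.GenotypeMatrix(genotypes=Z, animal_ids=ids, marker_map=mm)
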