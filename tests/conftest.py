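import logging

import numpy as np
import pandas as pd
import pytest

from cdev import SimConfig, reference_factors, simulate

# iterative normalizers log expected fallbacks/non-convergence; keep the
# test output readable
logging.getLogger("cdev").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def positive_matrix(rng, n, m, low=0.5, high=50.0):
    return rng.uniform(low, high, (n, m))


@pytest.fixture(scope="session")
def het_sim():
    """A mid-sized heterogeneous-fold-change simulation reused read-only."""
    return simulate(SimConfig(
        n_genes=4000, n_samples=(10, 10), de_fraction=0.5,
        mode="heterogeneous", seed=7,
    ))


@pytest.fixture(scope="session")
def het_truth_factors(het_sim):
    Y = het_sim.counts
    refs = Y.index[~het_sim.de_mask]
    return reference_factors(Y, refs).factors


def toy_counts():
    """A tiny deterministic count matrix with two spike-in rows."""
    genes = ["ERCC-00002", "ERCC-00003", "geneA", "geneB", "geneC"]
    data = np.array([
        [120, 130, 110, 125],
        [60, 55, 65, 58],
        [10, 500, 20, 400],
        [300, 20, 280, 25],
        [50, 45, 55, 60],
    ])
    return pd.DataFrame(data, index=genes, columns=["s1", "s2", "s3", "s4"])
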