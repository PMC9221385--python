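import numpy as np
import pandas as pd
import pytest

import baitsig as bs


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic cohort at the stated-world defaults (seed 1)."""
    return bs.generate_dataset(bs.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def derived(default_dataset):
    """BaitSignatureDeriver fitted on the default cohort."""
    m, _, truth = default_dataset
    return bs.BaitSignatureDeriver(baits=list(truth.bait_ids)).fit(m)


@pytest.fixture(scope="session")
def default_zmatrix(default_dataset):
    m, _, _ = default_dataset
    return bs.zscore(m)


@pytest.fixture
def toy_matrix():
    """6-sample toy log2 matrix with fixed integer rows."""
    values = pd.DataFrame(
        {
            "s1": [1, 2, 5, 3, 0, 7],
            "s2": [2, 3, 4, 1, 0, 7],
            "s3": [3, 4, 3, 4, 0, 7],
            "s4": [4, 5, 2, 2, 0, 7],
            "s5": [5, 6, 1, 5, 0, 7],
            "s6": [6, 7, 0, 0, 0, 7],
        },
        index=["bait", "twin", "anti", "noisy", "zero", "flat"],
        dtype=float,
    )
    return bs.ExpressionMatrix(values=values, scale="log2")


def random_log2_matrix(rng, n_genes, n_samples):
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(n_samples)]
    vals = rng.normal(8, 2, size=(n_genes, n_samples))
    return bs.ExpressionMatrix(
        values=pd.DataFrame(vals, index=genes, columns=samples), scale="log2"
    )
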