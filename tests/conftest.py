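import numpy as np
import pandas as pd
import pytest

from pifomics import CountMatrix, SimConfig, generate_counts


def make_matrix(values, proteins=None, n_high=None):
    """CountMatrix from a 2-D array; first half of columns are 'high'."""
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    if n_high is None:
        n_high = n_samp // 2
    proteins = proteins or [f"P{i}" for i in range(1, n_prot + 1)]
    samples = [f"h{i}" for i in range(1, n_high + 1)] + [
        f"l{i}" for i in range(1, n_samp - n_high + 1)
    ]
    counts = pd.DataFrame(values, index=pd.Index(proteins, name="protein"),
                          columns=samples)
    groups = pd.Series(["high"] * n_high + ["low"] * (n_samp - n_high),
                       index=counts.columns)
    return CountMatrix(counts, groups)


@pytest.fixture
def toy_matrix():
    return make_matrix(
        [
            [10, 12, 9, 11, 5, 6, 4, 5],
            [100, 90, 110, 95, 100, 105, 98, 99],
            [0, 1, 0, 2, 3, 0, 1, 0],
            [50, 55, 52, 48, 20, 22, 18, 21],
        ]
    )


@pytest.fixture(scope="session")
def sim_default():
    """One medium synthetic dataset reused by read-only tests."""
    cfg = SimConfig(n_proteins=400, n_compartment=80, seed=42)
    return generate_counts(cfg)
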