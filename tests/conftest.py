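import numpy as np
import pandas as pd
import pytest

from igomeprof._alphabet import N_AA
from igomeprof.composition import estimate_background
from igomeprof.gibbs import ClusteringState


@pytest.fixture(scope="session")
def uniform_q():
    return np.full(N_AA, 1.0 / N_AA)


@pytest.fixture(scope="session")
def nnk_bg():
    return estimate_background("nnk")


@pytest.fixture
def two_motif_state(uniform_q):
    """Deterministic state: two clusters of near-identical strong motifs."""
    peptides = (
        ["AAAAAAA", "AAAAAAC", "AAAAAAD", "AAAAAAE", "AAAAAAF"]
        + ["WWWWWWW", "WWWWWWC", "WWWWWWD", "WWWWWWE", "WWWWWWF"]
    )
    assignment = np.array([0] * 5 + [1] * 5)
    return ClusteringState(
        peptides=peptides, assignment=assignment, G=2, q=uniform_q, beta=10.0, seed=0
    )


@pytest.fixture
def small_matrix():
    """6-sample, 8-peptide reactivity matrix with simple structure."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(8.0, 0.5, (8, 6)),
        index=[f"p{i}" for i in range(8)],
        columns=[f"s{j}" for j in range(6)],
    )
    meta = pd.DataFrame(
        {
            "diagnosis": ["GBM"] * 3 + ["C"] * 3,
            "batch": ["G", "P", "G", "P", "G", "P"],
        },
        index=values.columns,
    )
    return values, meta
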