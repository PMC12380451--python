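"""Shared fixtures: small model-generated datasets with known truth."""

from __future__ import annotations

import numpy as np
import pytest

from scinsight2 import SimulationConfig, config_from_preset, simulate_dataset
from scinsight2.estimation import constrain_loadings
from scinsight2.model_core import ExpressionDataset


@pytest.fixture(scope="session")
def smoke_truth():
    """Scaled-down multi-subject simulation (1000 cells x 400 genes)."""
    return simulate_dataset(config_from_preset("setting1-smoke", seed=1))


@pytest.fixture(scope="session")
def tiny_truth():
    """A very small simulation for fast structural checks."""
    cfg = SimulationConfig(
        K=4,
        cells_per_subject=40,
        M=80,
        P_true=2,
        n_affected_per_covariate=20,
        cell_type_mean_matrix=np.array(
            [[1, 0], [0, 1], [1, 1], [0, 0], [0.5, 1], [1, 0.5], [0.5, 0.5], [0, 0.5]]
        ),
        seed=42,
    )
    return simulate_dataset(cfg)


def make_model_dataset(seed: int, K: int = 10, cells_per_subject: int = 30, M: int = 120, P: int = 2):
    """Data drawn exactly from the GLLVM (Gaussian embeddings, Poisson counts).

    Subject-level design has three columns: a standardized continuous
    covariate and a binary covariate that each affect 30 genes with
    coefficients of magnitude Uniform(1, 1.5), plus a continuous null
    covariate with all-zero coefficients.
    """
    rng = np.random.default_rng(seed)
    N = K * cells_per_subject
    Xs = np.column_stack(
        [rng.standard_normal(K), rng.choice([0.0, 1.0], K), rng.standard_normal(K)]
    )
    for c in (0, 2):
        Xs[:, c] = (Xs[:, c] - Xs[:, c].mean()) / Xs[:, c].std(ddof=1)
    X = np.repeat(Xs, cells_per_subject, axis=0)
    B_true = np.zeros((3, M))
    g1 = rng.choice(M, 30, replace=False)
    g2 = rng.choice(M, 30, replace=False)
    B_true[0, g1] = rng.choice([-1, 1], 30) * rng.uniform(1, 1.5, 30)
    B_true[1, g2] = rng.choice([-1, 1], 30) * rng.uniform(1, 1.5, 30)
    beta0 = rng.standard_normal(M) + 1.0
    Lam = constrain_loadings(rng.standard_normal((P, M)) / np.sqrt(P))
    U_true = rng.normal(0.0, 0.5, (N, P))
    eta = beta0[None, :] + X @ B_true + U_true @ Lam
    Y = rng.poisson(np.exp(np.minimum(eta, 12)))
    data = ExpressionDataset(
        counts=Y,
        cell_ids=np.array([f"c{i}" for i in range(N)]),
        gene_ids=np.array([f"g{j}" for j in range(M)]),
        sample_of_cell=np.repeat(np.arange(K), cells_per_subject),
    )
    truth = {
        "X": X,
        "B_true": B_true,
        "beta0": beta0,
        "Lambda": Lam,
        "U_true": U_true,
        "affected": {"cont": g1, "binary": g2},
        "null_row": 2,
    }
    return data, truth


@pytest.fixture(scope="session")
def model_dataset():
    return make_model_dataset(seed=11)
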