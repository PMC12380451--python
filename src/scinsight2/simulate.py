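"""Synthetic scRNA-seq generator with full ground truth.

Emulates a multi-subject study: K subjects each contribute a sample of cells
with subject-level covariates (age, gender, disease condition, BMI) that
shift the expression of a subset of genes, while cell identity lives in a
low-dimensional metagene space.  Counts are multinomial per cell at a drawn
library size, with gene probabilities softmax(eta) from the same linear
predictor the model assumes — so the generator is model-consistent up to the
cell-type structure of the embeddings (a deliberate deviation from the
Gaussian embedding prior).

Three settings vary the cell-type composition:
  1. all eight types at 12.5% in every subject;
  2. types 1 and 2 exclusive to the healthy / mild conditions respectively;
  3. types 1 and 2 with age-dependent abundance.

Presets scale the covariate effect sizes (``setting1-strong``: |coef| in
(1.5, 2); ``setting1-stronger``: (2, 2.5)) or induce collinearity between
age and condition (``setting1-collinear``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .estimation import constrain_loadings
from .model_core import DesignMatrix, ExpressionDataset, build_design

logger = logging.getLogger("scinsight2")

N_CELL_TYPES = 8

#: covariate type declaration used by every simulated design
COVARIATE_SPEC = {
    "age": "continuous",
    "gender": "categorical",
    "condition": "categorical",
    "bmi": "continuous",
}
CONDITION_LEVELS = ("healthy", "mild", "severe")


def _default_type_means(P: int, separation: float) -> np.ndarray:
    """8 x P matrix of sparse type codes: each type high on 1-2 factors."""
    codes = [(0,), (1,), (2,), (3,), (4,), (0, 1), (1, 2), (3, 4)]
    M = np.zeros((N_CELL_TYPES, P))
    for t, axes in enumerate(codes):
        for a in axes:
            M[t, a % P] = separation
    return M


@dataclass
class SimulationConfig:
    setting: int = 1
    K: int = 10
    cells_per_subject: int = 500
    M: int = 2000
    P_true: int = 5
    n_affected_per_covariate: int = 300
    coef_range: tuple[float, float] = (1.0, 1.5)
    embedding_sd: float = 0.1
    separation: float = 1.0
    cell_type_mean_matrix: np.ndarray | None = None
    library_meanlog: float = 7.5
    library_sdlog: float = 0.5
    library_sizes_file: str | None = None
    covariate_assignment: str = "random"  # or "collinear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.setting not in (1, 2, 3):
            raise ValueError("setting must be 1, 2 or 3")
        lo, hi = self.coef_range
        if not lo < hi:
            raise ValueError("coef_range must satisfy lo < hi")
        if self.n_affected_per_covariate > self.M:
            raise ValueError("cannot affect more genes than exist")
        if self.cell_type_mean_matrix is None:
            self.cell_type_mean_matrix = _default_type_means(self.P_true, self.separation)
        self.cell_type_mean_matrix = np.asarray(self.cell_type_mean_matrix, dtype=float)
        if self.cell_type_mean_matrix.shape != (N_CELL_TYPES, self.P_true):
            raise ValueError("cell_type_mean_matrix must be 8 x P_true")


PRESETS: dict[str, dict] = {
    "setting1": {},
    "setting2": {"setting": 2},
    "setting3": {"setting": 3},
    "setting1-strong": {"coef_range": (1.5, 2.0)},
    "setting1-stronger": {"coef_range": (2.0, 2.5)},
    "setting1-collinear": {"covariate_assignment": "collinear"},
    # scaled-down smoke configuration for fast end-to-end runs
    "setting1-smoke": {"cells_per_subject": 100, "M": 400, "n_affected_per_covariate": 100},
    "setting1-strong-smoke": {
        "cells_per_subject": 100,
        "M": 400,
        "n_affected_per_covariate": 100,
        "coef_range": (1.5, 2.0),
    },
}


def config_from_preset(preset: str, **overrides) -> SimulationConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[preset])
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class SimulationTruth:
    dataset: ExpressionDataset
    design: DesignMatrix
    covariates: pd.DataFrame
    cell_types: np.ndarray
    U_true: np.ndarray
    beta0_true: np.ndarray
    B_true: np.ndarray
    Lambda_true: np.ndarray
    library_sizes: np.ndarray
    affected_genes: dict[str, np.ndarray] = field(default_factory=dict)
    config: SimulationConfig | None = None


# -- simulation steps ----------------------------------------------------------


def simulate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw subject-level covariates: age U(20,70), BMI U(16,24), gender,
    3-level condition.  Collinear assignment ties condition to age rank
    (4 youngest -> first level, middle 4 -> second, 2 oldest -> third) and is
    defined only for K = 10 subjects."""
    K = config.K
    if K < 2:
        raise ValueError("need at least 2 subjects")
    age = rng.uniform(20, 70, size=K)
    bmi = rng.uniform(16, 24, size=K)
    gender = rng.choice(["F", "M"], size=K)
    if config.covariate_assignment == "random":
        condition = rng.choice(list(CONDITION_LEVELS), size=K)
    elif config.covariate_assignment == "collinear":
        if K != 10:
            raise ValueError("collinear assignment is defined for exactly 10 subjects")
        condition = np.empty(K, dtype=object)
        order = np.argsort(age, kind="stable")
        condition[order[:4]] = CONDITION_LEVELS[0]
        condition[order[4:8]] = CONDITION_LEVELS[1]
        condition[order[8:]] = CONDITION_LEVELS[2]
    else:
        raise ValueError(f"unknown covariate_assignment {config.covariate_assignment!r}")
    return pd.DataFrame(
        {"age": age, "gender": gender, "condition": condition, "bmi": bmi},
        index=pd.Index([f"subject{k + 1}" for k in range(K)], name="sample_id"),
    )


def simulate_coefficients(
    config: SimulationConfig,
    design: DesignMatrix,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Gene intercepts N(0,1); for each of age, gender and BMI a random set of
    genes gets coefficients drawn from +-Uniform(coef_range) with equal sign
    probability; condition coefficients are identically zero (a planted null
    covariate)."""
    M = config.M
    lo, hi = config.coef_range
    beta0 = rng.standard_normal(M)
    D = design.n_covariate_columns
    B = np.zeros((D, M))
    affected: dict[str, np.ndarray] = {}
    for cov in ("age", "gender", "bmi"):
        cols = design.columns_of(cov)
        genes = rng.choice(M, size=config.n_affected_per_covariate, replace=False)
        affected[cov] = np.sort(genes)
        mag = rng.uniform(lo, hi, size=len(genes))
        sign = rng.choice([-1.0, 1.0], size=len(genes))
        for c in cols:
            B[c, genes] = sign * mag
    # condition columns stay zero
    return beta0, B, affected


def _type_probabilities(config: SimulationConfig, covariates: pd.DataFrame) -> np.ndarray:
    """Per-subject cell-type probability rows (K x 8) for the chosen setting."""
    K = config.K
    probs = np.full((K, N_CELL_TYPES), 1.0 / N_CELL_TYPES)
    if config.setting == 2:
        for k, cond in enumerate(covariates["condition"]):
            row = np.full(N_CELL_TYPES, 1.0 / 7)
            if cond == "healthy":
                row[1] = 0.0
            elif cond == "mild":
                row[0] = 0.0
            else:  # severe: types 1 and 2 absent
                row = np.full(N_CELL_TYPES, 1.0 / 6)
                row[0] = row[1] = 0.0
            probs[k] = row
    elif config.setting == 3:
        for k, age in enumerate(covariates["age"]):
            row = np.full(N_CELL_TYPES, 0.1)
            if age < 30:
                row[0] = 0.3
            elif age < 45:
                row[0] = row[1] = 0.2
            else:
                row[1] = 0.3
            probs[k] = row
    if not np.allclose(probs.sum(axis=1), 1.0):
        raise ValueError("cell-type proportions do not sum to 1")
    return probs


def simulate_cells(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw cell types per subject and embeddings N(mean[type], embedding_sd)."""
    probs = _type_probabilities(config, covariates)
    K, n = config.K, config.cells_per_subject
    types = np.concatenate([rng.choice(N_CELL_TYPES, size=n, p=probs[k]) for k in range(K)])
    sample_of_cell = np.repeat(covariates.index.to_numpy(), n)
    means = config.cell_type_mean_matrix[types]
    U = rng.normal(means, config.embedding_sd)
    return types, U, sample_of_cell


def simulate_loadings(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Dense Gaussian loadings N(0, 1/P) projected to the identifiability
    constraint (upper-triangular leading block, positive diagonal)."""
    P, M = config.P_true, config.M
    raw = rng.standard_normal((P, M)) / np.sqrt(P)
    Lam = constrain_loadings(raw)
    return Lam


def simulate_library_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Library sizes: user-supplied empirical values (resampled) or lognormal."""
    N = config.K * config.cells_per_subject
    if config.library_sizes_file:
        pool = np.loadtxt(config.library_sizes_file, dtype=float).ravel()
        sizes = rng.choice(pool, size=N, replace=True)
    else:
        sizes = rng.lognormal(config.library_meanlog, config.library_sdlog, size=N)
    return np.maximum(np.round(sizes).astype(np.int64), 1)


def simulate_counts(
    eta: np.ndarray,
    library_sizes: np.ndarray,
    rng: np.random.Generator,
) -> sp.csr_matrix:
    """One multinomial draw per cell: size = library size, p = softmax(eta).

    ``eta`` here excludes the log size-factor offset: softmax is invariant to
    per-cell additive constants, so the offset is absorbed by the multinomial
    size.  Row sums equal the library sizes exactly.
    """
    eta = np.atleast_2d(eta)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    z = eta - eta.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    N, M = p.shape
    rows = []
    for i in range(N):
        rows.append(sp.csr_matrix(rng.multinomial(int(library_sizes[i]), p[i])))
    return sp.vstack(rows).tocsr()


def simulate_dataset(config: SimulationConfig) -> SimulationTruth:
    """Run the full generative design and package counts plus ground truth."""
    rng = np.random.default_rng(config.seed)
    covariates = simulate_covariates(config, rng)
    design_subjects = build_design(
        covariates,
        covariates.index.to_numpy(),
        COVARIATE_SPEC,
    )
    types, U, sample_of_cell = simulate_cells(config, covariates, rng)
    design = build_design(covariates, sample_of_cell, COVARIATE_SPEC)
    beta0, B, affected = simulate_coefficients(config, design_subjects, rng)
    Lam = simulate_loadings(config, rng)
    ell = simulate_library_sizes(config, rng)
    eta = beta0[None, :] + design.X @ B + U @ Lam  # no size offset: cancels in softmax
    counts = simulate_counts(eta, ell, rng)
    N = counts.shape[0]
    dataset = ExpressionDataset(
        counts=counts,
        cell_ids=np.array([f"cell{i + 1}" for i in range(N)]),
        gene_ids=np.array([f"gene{j + 1}" for j in range(config.M)]),
        sample_of_cell=sample_of_cell,
    )
    return SimulationTruth(
        dataset=dataset,
        design=design,
        covariates=covariates,
        cell_types=types,
        U_true=U,
        beta0_true=beta0,
        B_true=B,
        Lambda_true=Lam,
        library_sizes=ell,
        affected_genes=affected,
        config=replace(config),
    )
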