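"""Core data containers and the mean model of the Poisson GLLVM.

The model treats each count ``y_ij`` (cell i, gene j) as Poisson with a
log-link mean

    log(mu_ij) = eta_ij = beta0_j + log(s_i) + x_i' beta_j + u_i' lambda_j

where ``s_i`` is the cell's library-size factor, ``x_i`` the subject-level
covariate row inherited by the cell, ``u_i`` the cell's latent metagene
scores and ``lambda_j`` the gene's loadings on the metagenes.  This module
holds the containers for the data (:class:`ExpressionDataset`), the covariate
design (:class:`DesignMatrix`) and the estimable parameters
(:class:`ModelParams`), plus the deterministic pieces of the model: size
factors, covariate encoding and the linear predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("scinsight2")

# -- configuration defaults (shared across modules) --------------------------

#: cap on the linear predictor; exp(30) ~ 1e13 keeps mu finite in float64
ETA_CAP: float = 30.0
#: floor for the embedding prior SD
SIGMA_FLOOR: float = 1e-4
#: load-time filters emulating standard scRNA-seq QC
MIN_CELLS_PER_GENE: int = 3
MIN_GENES_PER_CELL: int = 200


# -- containers ---------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Concatenated counts for N cells x M genes with sample membership.

    ``counts`` may be dense or CSR sparse; entries are non-negative integers.
    ``library_sizes`` are the per-cell row sums and ``size_factors`` their
    ratio to the median library size.
    """

    counts: "sp.spmatrix | np.ndarray"
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    sample_of_cell: np.ndarray
    library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]
    size_factors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        self.gene_ids = np.asarray(self.gene_ids)
        self.sample_of_cell = np.asarray(self.sample_of_cell)
        n, m = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != m:
            raise ValueError(
                f"metadata lengths ({len(self.cell_ids)} cells, "
                f"{len(self.gene_ids)} genes) do not match counts shape {self.counts.shape}"
            )
        if len(self.sample_of_cell) != n:
            raise ValueError("sample_of_cell length does not match cell count")
        if sp.issparse(self.counts):
            self.counts = self.counts.tocsr()
            if self.counts.nnz and self.counts.data.min() < 0:
                raise ValueError("counts contain negative entries")
            rowsums = np.asarray(self.counts.sum(axis=1)).ravel()
        else:
            self.counts = np.asarray(self.counts)
            if self.counts.size and self.counts.min() < 0:
                raise ValueError("counts contain negative entries")
            rowsums = self.counts.sum(axis=1)
        if self.library_sizes is None:
            self.library_sizes = rowsums.astype(np.int64)
        if self.size_factors is None:
            self.size_factors = compute_size_factors(self.library_sizes)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def samples(self) -> np.ndarray:
        return np.unique(self.sample_of_cell)

    def dense_counts(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)


@dataclass
class DesignMatrix:
    """Cell-level covariate design X (N x D) with per-column provenance.

    Continuous covariates are standardized over the K subjects (not over
    cells) and broadcast; categorical covariates are reference-coded dummies.
    ``column_meta`` records, per column, the source covariate, its kind and
    (for dummies) the encoded level; ``standardization`` maps each continuous
    covariate to its subject-level (mean, sd).
    """

    X: np.ndarray
    column_meta: list[dict]
    standardization: dict[str, tuple[float, float]]
    reference_levels: dict[str, str]

    @property
    def n_covariate_columns(self) -> int:
        return self.X.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [m["name"] for m in self.column_meta]

    def columns_of(self, covariate: str) -> list[int]:
        """Indices of design columns derived from one raw covariate."""
        return [i for i, m in enumerate(self.column_meta) if m["covariate"] == covariate]


@dataclass
class ModelParams:
    """Estimable quantities of the GLLVM.

    ``Lambda`` satisfies the identifiability constraint: entries below the
    leading P x P diagonal block are zero and diagonal entries are positive
    (upper-triangular leading block).  ``sigma`` is the prior SD of the cell
    embeddings, floored at :data:`SIGMA_FLOOR`.
    """

    beta0: np.ndarray  # (M,)
    B: np.ndarray  # (D, M)
    Lambda: np.ndarray  # (P, M)
    sigma: float
    U: np.ndarray  # (N, P)

    def __post_init__(self) -> None:
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, dtype=float))
        self.U = np.atleast_2d(np.asarray(self.U, dtype=float))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        P, M = self.Lambda.shape
        if P > min(self.U.shape[0], M):
            raise ValueError("P cannot exceed min(N, M)")
        if self.B.shape[1] != M or len(self.beta0) != M or self.U.shape[1] != P:
            raise ValueError("inconsistent parameter dimensions")

    @property
    def P(self) -> int:
        return self.Lambda.shape[0]

    def check_loading_constraint(self, atol: float = 0.0) -> bool:
        P = self.P
        lower = np.tril(self.Lambda[:, :P], k=-1)
        return bool(
            np.all(np.abs(lower) <= atol) and np.all(np.diag(self.Lambda[:, :P]) > 0)
        )


# -- operations ---------------------------------------------------------------


def compute_size_factors(library_sizes: Sequence[int] | np.ndarray) -> np.ndarray:
    """Library-size factors s_i = l_i / median(l)."""
    ell = np.asarray(library_sizes, dtype=float)
    bad = np.where(ell <= 0)[0]
    if bad.size:
        raise ValueError(
            f"library sizes must be positive; offending cell indices: {bad[:10].tolist()}"
        )
    return ell / np.median(ell)


def build_design(
    subject_covariates: pd.DataFrame,
    sample_of_cell: Sequence | np.ndarray,
    spec: Mapping[str, str],
    reference_levels: Mapping[str, str] | None = None,
) -> DesignMatrix:
    """Encode subject-level covariates into a cell-level design matrix.

    Parameters
    ----------
    subject_covariates
        K subjects x raw covariates, indexed by sample/subject id.
    sample_of_cell
        Length-N sample label per cell; every label must index the table.
    spec
        Mapping covariate name -> ``"continuous"`` | ``"categorical"``.
    reference_levels
        Optional per-categorical reference level (default: first level in
        lexicographic order).

    Continuous covariates are standardized over the K subject values (sample
    SD, denominator K-1) and broadcast to cells; categorical covariates are
    dummy-coded against the reference level.
    """
    sample_of_cell = np.asarray(sample_of_cell)
    missing = set(np.unique(sample_of_cell)) - set(subject_covariates.index)
    if missing:
        raise ValueError(f"sample labels not in covariate table: {sorted(missing)!r}")
    reference_levels = dict(reference_levels or {})

    subj_cols: list[np.ndarray] = []
    column_meta: list[dict] = []
    standardization: dict[str, tuple[float, float]] = {}
    used_refs: dict[str, str] = {}

    for cov, kind in spec.items():
        if cov not in subject_covariates.columns:
            raise ValueError(f"covariate {cov!r} missing from subject table")
        values = subject_covariates[cov]
        if values.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values")
        if kind == "continuous":
            v = values.to_numpy(dtype=float)
            mean = float(v.mean())
            sd = float(v.std(ddof=1)) if len(v) > 1 else 1.0
            if sd == 0:
                logger.warning("continuous covariate %r is constant; column dropped", cov)
                continue
            subj_cols.append((v - mean) / sd)
            column_meta.append({"name": cov, "covariate": cov, "kind": "continuous"})
            standardization[cov] = (mean, sd)
        elif kind == "categorical":
            levels = sorted(values.astype(str).unique())
            if len(levels) < 2:
                logger.warning(
                    "categorical covariate %r has a single level; dropped", cov
                )
                continue
            ref = str(reference_levels.get(cov, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not a level of {cov!r}")
            used_refs[cov] = ref
            for lev in levels:
                if lev == ref:
                    continue
                subj_cols.append((values.astype(str) == lev).to_numpy(dtype=float))
                column_meta.append(
                    {
                        "name": f"{cov}[{lev}]",
                        "covariate": cov,
                        "kind": "dummy",
                        "level": lev,
                        "reference": ref,
                    }
                )
        else:
            raise ValueError(f"unknown covariate type {kind!r} for {cov!r}")

    X_subj = (
        np.column_stack(subj_cols) if subj_cols else np.empty((len(subject_covariates), 0))
    )
    row_of = {s: i for i, s in enumerate(subject_covariates.index)}
    idx = np.array([row_of[s] for s in sample_of_cell])
    return DesignMatrix(
        X=X_subj[idx],
        column_meta=column_meta,
        standardization=standardization,
        reference_levels=used_refs,
    )


def linear_predictor(
    params: ModelParams,
    design: DesignMatrix | np.ndarray,
    size_factors: np.ndarray,
    eta_cap: float = ETA_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate eta and mu = exp(eta) of the mean model for all cells/genes.

    eta_ij = beta0_j + log(s_i) + x_i' beta_j + u_i' lambda_j, clipped at
    ``eta_cap`` (with a warning) to guard against overflow early in
    optimization.
    """
    X = design.X if isinstance(design, DesignMatrix) else np.atleast_2d(design)
    s = np.asarray(size_factors, dtype=float)
    N = X.shape[0]
    if params.U.shape[0] != N or len(s) != N:
        raise ValueError("cell dimension mismatch between params, design and size factors")
    if X.shape[1] != params.B.shape[0]:
        raise ValueError(
            f"design has {X.shape[1]} columns but B expects {params.B.shape[0]}"
        )
    eta = params.beta0[None, :] + np.log(s)[:, None] + X @ params.B + params.U @ params.Lambda
    if np.max(eta, initial=-np.inf) > eta_cap:
        logger.warning("linear predictor clipped at eta_cap=%.1f", eta_cap)
        eta = np.minimum(eta, eta_cap)
    return eta, np.exp(eta)


def filter_dataset(
    dataset: ExpressionDataset,
    min_cells_per_gene: int = MIN_CELLS_PER_GENE,
    min_genes_per_cell: int = MIN_GENES_PER_CELL,
) -> ExpressionDataset:
    """QC filter: drop genes seen in too few cells and shallow cells.

    Genes expressed in fewer than ``min_cells_per_gene`` cells and cells with
    fewer than ``min_genes_per_cell`` expressed genes are removed (gene filter
    first, then the cell filter, then zero-count leftovers).  Size factors are
    recomputed on the filtered matrix.
    """
    Y = dataset.counts
    if sp.issparse(Y):
        cells_per_gene = np.asarray((Y > 0).sum(axis=0)).ravel()
    else:
        cells_per_gene = (Y > 0).sum(axis=0)
    gene_keep = cells_per_gene >= min_cells_per_gene
    Y = Y[:, gene_keep]
    if sp.issparse(Y):
        genes_per_cell = np.asarray((Y > 0).sum(axis=1)).ravel()
    else:
        genes_per_cell = (Y > 0).sum(axis=1)
    cell_keep = (genes_per_cell >= min_genes_per_cell) & (genes_per_cell > 0)
    n_drop_c = int((~cell_keep).sum())
    n_drop_g = int((~gene_keep).sum())
    if n_drop_c or n_drop_g:
        logger.info(
            "filtering removed %d genes (<%d cells) and %d cells (<%d genes)",
            n_drop_g,
            min_cells_per_gene,
            n_drop_c,
            min_genes_per_cell,
        )
    return ExpressionDataset(
        counts=Y[cell_keep],
        cell_ids=dataset.cell_ids[cell_keep],
        gene_ids=dataset.gene_ids[gene_keep],
        sample_of_cell=dataset.sample_of_cell[cell_keep],
    )


def variance_rank_genes(dataset: ExpressionDataset, n_top: int) -> np.ndarray:
    """Plain variance-rank helper: indices of the ``n_top`` most variable genes."""
    Y = dataset.counts
    if sp.issparse(Y):
        mean = np.asarray(Y.mean(axis=0)).ravel()
        sq = np.asarray(Y.multiply(Y).mean(axis=0)).ravel()
        var = sq - mean**2
    else:
        var = Y.var(axis=0)
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:n_top])
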