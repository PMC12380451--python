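"""Readers/writers for standard formats, run manifests, and logging setup.

Counts travel as Matrix Market coordinate files plus tab-delimited cell
metadata (cell_id, sample_id) and a subject covariate table (sample_id +
covariate columns).  The internal orientation is cells x genes; genes x
cells files (the common 10x convention) are auto-detected from the metadata
row counts and transposed with a log line.  Every CLI run writes a JSON
manifest (command, resolved configuration, seeds, input digests, version,
timestamps) sufficient to re-run it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .estimation import FitResult
from .model_core import (
    MIN_CELLS_PER_GENE,
    MIN_GENES_PER_CELL,
    DesignMatrix,
    ExpressionDataset,
    build_design,
    filter_dataset,
)

logger = logging.getLogger("scinsight2")

SEP = "\t"


def setup_logging(level: str = "INFO", logfile: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    root = logging.getLogger("scinsight2")
    root.setLevel(getattr(logging, level.upper()))
    root.handlers = []
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, command: str, config: dict, seeds: dict, inputs: list[str]) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): _digest(p) for p in inputs},
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


# -- dataset I/O ---------------------------------------------------------------


def load_dataset(
    counts_path: str | Path,
    cell_meta_path: str | Path,
    covariates_path: str | Path,
    spec: dict[str, str],
    min_cells_per_gene: int = MIN_CELLS_PER_GENE,
    min_genes_per_cell: int = MIN_GENES_PER_CELL,
) -> tuple[ExpressionDataset, DesignMatrix]:
    """Load counts + metadata, apply QC filters, build size factors and design."""
    mat = sio.mmread(str(counts_path)).tocsr()
    cells = pd.read_csv(cell_meta_path, sep=SEP)
    if not {"cell_id", "sample_id"} <= set(cells.columns):
        raise ValueError("cell metadata must have cell_id and sample_id columns")
    n_cells = len(cells)
    if mat.shape[0] == n_cells:
        pass
    elif mat.shape[1] == n_cells:
        logger.info("counts are genes x cells (%s); transposing", mat.shape)
        mat = mat.T.tocsr()
    else:
        raise ValueError(
            f"counts shape {mat.shape} matches neither orientation for {n_cells} cells"
        )
    gene_ids = np.array([f"gene{j + 1}" for j in range(mat.shape[1])])
    genes_path = Path(str(counts_path)).with_suffix(".genes.tsv")
    if genes_path.exists():
        gene_ids = pd.read_csv(genes_path, sep=SEP)["gene_id"].to_numpy()
        if len(gene_ids) != mat.shape[1]:
            raise ValueError(
                f"gene metadata rows ({len(gene_ids)}) do not match counts genes ({mat.shape[1]})"
            )
    covariates = pd.read_csv(covariates_path, sep=SEP, index_col="sample_id")
    dataset = ExpressionDataset(
        counts=mat,
        cell_ids=cells["cell_id"].to_numpy(),
        gene_ids=gene_ids,
        sample_of_cell=cells["sample_id"].to_numpy(),
    )
    logger.info("loaded %d cells x %d genes", dataset.n_cells, dataset.n_genes)
    dataset = filter_dataset(dataset, min_cells_per_gene, min_genes_per_cell)
    logger.info("after filtering: %d cells x %d genes", dataset.n_cells, dataset.n_genes)
    design = build_design(covariates, dataset.sample_of_cell, spec)
    return dataset, design


def save_dataset(truth_or_dataset, out_dir: str | Path) -> None:
    """Write an ExpressionDataset (or SimulationTruth) as MTX + TSV files."""
    from .simulate import SimulationTruth

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = truth_or_dataset if isinstance(truth_or_dataset, SimulationTruth) else None
    dataset = truth.dataset if truth else truth_or_dataset
    counts = dataset.counts if sp.issparse(dataset.counts) else sp.csr_matrix(dataset.counts)
    sio.mmwrite(str(out_dir / "counts.mtx"), counts.tocoo(), field="integer")
    pd.DataFrame({"cell_id": dataset.cell_ids, "sample_id": dataset.sample_of_cell}).to_csv(
        out_dir / "cells.tsv", sep=SEP, index=False
    )
    pd.DataFrame({"gene_id": dataset.gene_ids}).to_csv(
        out_dir / "counts.genes.tsv", sep=SEP, index=False
    )
    if truth is not None:
        truth.covariates.to_csv(out_dir / "covariates.tsv", sep=SEP)
        pd.DataFrame(
            {"cell_id": dataset.cell_ids, "cell_type": truth.cell_types}
        ).to_csv(out_dir / "truth_cell_types.tsv", sep=SEP, index=False)
        np.savetxt(out_dir / "truth_U.tsv", truth.U_true, delimiter=SEP)
        np.savetxt(out_dir / "truth_Lambda.tsv", truth.Lambda_true, delimiter=SEP)
        np.savetxt(out_dir / "truth_beta0.tsv", truth.beta0_true, delimiter=SEP)
        np.savetxt(out_dir / "truth_B.tsv", truth.B_true, delimiter=SEP)


def _write_matrix(path: Path, mat: np.ndarray, index, columns) -> None:
    pd.DataFrame(np.atleast_2d(mat), index=index, columns=columns).to_csv(
        path, sep=SEP, float_format="%.12g"
    )


def save_fit(
    result: FitResult,
    out_dir: str | Path,
    cell_ids: np.ndarray,
    gene_ids: np.ndarray,
    design: DesignMatrix | None = None,
    force: bool = False,
) -> None:
    """Write fitted parameters as headered delimited text plus a manifest stub."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty; pass force=True/--force")
    out_dir.mkdir(parents=True, exist_ok=True)
    p = result.params
    P = p.P
    factors = [f"metagene{q + 1}" for q in range(P)]
    _write_matrix(out_dir / "U.tsv", p.U, cell_ids, factors)
    _write_matrix(out_dir / "Lambda.tsv", p.Lambda, factors, gene_ids)
    _write_matrix(out_dir / "beta0.tsv", p.beta0[None, :], ["beta0"], gene_ids)
    cov_cols = design.column_names if design is not None else [f"x{d + 1}" for d in range(p.B.shape[0])]
    _write_matrix(out_dir / "B.tsv", p.B, cov_cols, gene_ids)
    np.savetxt(out_dir / "objective_trace.tsv", result.objective_trace, delimiter=SEP)
    (out_dir / "fit.json").write_text(
        json.dumps(
            {
                "sigma": p.sigma,
                "P": P,
                "converged": result.converged,
                "n_iter": result.n_iter,
                "seed": result.seed,
                "settings": dataclasses.asdict(result.settings),
            },
            indent=2,
        )
    )


def load_fit_params(out_dir: str | Path):
    """Reload parameters written by :func:`save_fit` as a ModelParams."""
    from .model_core import ModelParams

    out_dir = Path(out_dir)
    U = pd.read_csv(out_dir / "U.tsv", sep=SEP, index_col=0)
    Lam = pd.read_csv(out_dir / "Lambda.tsv", sep=SEP, index_col=0)
    beta0 = pd.read_csv(out_dir / "beta0.tsv", sep=SEP, index_col=0)
    B = pd.read_csv(out_dir / "B.tsv", sep=SEP, index_col=0)
    meta = json.loads((out_dir / "fit.json").read_text())
    return ModelParams(
        beta0=beta0.to_numpy().ravel(),
        B=B.to_numpy(),
        Lambda=Lam.to_numpy(),
        sigma=meta["sigma"],
        U=U.to_numpy(),
    )
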