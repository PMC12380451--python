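"""Choosing the metagene number P by clustering-stability consensus.

For each candidate P the model is fitted B times from differently seeded
initializations; each fit is normalized and clustered, and the B binary
cell-cell connectivity matrices are averaged into a consensus matrix.  The
consensus index

    E_p = - sum_ij Cbar_ij log2(Cbar_ij)        (0 log 0 := 0)

is zero when every pair of cells is either always or never co-clustered and
grows with instability.  Candidates whose index is lower than both neighbors
form the admissible set; the smallest such candidate is selected (a
parsimony preference).  Endpoints are admitted when lower than their single
neighbor; on a profile with no local minimum the global minimum is returned
with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .estimation import FitOptions, fit
from .model_core import DesignMatrix, ExpressionDataset
from .postprocess import cluster_cells, normalize_embeddings

logger = logging.getLogger("scinsight2")

#: above this many cells, consensus matrices are computed on a seeded subsample
CONSENSUS_MAX_CELLS = 5000


@dataclass
class ConsensusSummary:
    candidates: list[int]
    runs_per_candidate: int
    labels: dict[int, list[np.ndarray]]
    consensus: dict[int, np.ndarray]
    index: dict[int, float]
    selected: int
    n_completed: dict[int, int] = field(default_factory=dict)


def connectivity_matrix(labels: np.ndarray) -> np.ndarray:
    """Binary co-membership matrix: C_ij = 1 iff labels[i] == labels[j]."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_matrix(labelings: list[np.ndarray]) -> np.ndarray:
    """Mean of the runs' binary connectivity matrices."""
    if not labelings:
        raise ValueError("need at least one labeling")
    n = len(labelings[0])
    C = np.zeros((n, n))
    for lab in labelings:
        if len(lab) != n:
            raise ValueError("labelings have inconsistent lengths")
        C += connectivity_matrix(lab)
    return C / len(labelings)


def consensus_index(labelings: list[np.ndarray]) -> float:
    """Entropy of the consensus matrix over all N^2 entries (base 2)."""
    C = consensus_matrix(labelings)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(C > 0, C * np.log2(np.where(C > 0, C, 1.0)), 0.0)
    return float(-terms.sum())


def select_P(candidates: list[int], indices: list[float]) -> int:
    """Smallest candidate whose consensus index is a local minimum.

    Endpoints qualify when lower than their single neighbor.  If no candidate
    qualifies, the global-minimum candidate is returned with a warning.
    """
    candidates = list(candidates)
    indices = list(indices)
    if len(candidates) != len(indices):
        raise ValueError("candidates and indices must have equal length")
    if any(b <= a for a, b in zip(candidates, candidates[1:])):
        raise ValueError("candidates must be strictly increasing")
    if len(candidates) == 0:
        raise ValueError("no candidates")
    if len(candidates) == 1:
        logger.warning("only one candidate supplied; selecting it trivially")
        return candidates[0]
    admissible = []
    for i, e in enumerate(indices):
        lower_prev = i == 0 or e < indices[i - 1]
        lower_next = i == len(indices) - 1 or e < indices[i + 1]
        if lower_prev and lower_next:
            admissible.append(candidates[i])
    if not admissible:
        best = candidates[int(np.argmin(indices))]
        logger.warning("no local minimum in consensus indices; falling back to global minimum P=%d", best)
        return best
    return min(admissible)


def run_selection(
    data: ExpressionDataset,
    design: DesignMatrix | np.ndarray,
    candidates: list[int],
    B: int = 10,
    base_seed: int = 0,
    opts: FitOptions | None = None,
    cluster_k: int = 50,
    resolution: float = 1.0,
) -> ConsensusSummary:
    """Fit each candidate P with B seeds, cluster, and pick P by consensus.

    Run b of any candidate uses seed ``base_seed + b`` for both the fit
    initialization and the Louvain step.  A failed fit is recorded and
    skipped; a candidate needs at least B/2 completed runs to stay in the
    race.  With B = 1 every candidate is trivially self-consistent (E_p = 0)
    and selection degenerates to the smallest candidate.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    if B == 1:
        logger.warning("B=1: consensus indices are identically 0; selection degenerates to min(A)")
    N = data.n_cells
    if N > CONSENSUS_MAX_CELLS:
        sub_rng = np.random.default_rng(base_seed)
        subsample = np.sort(sub_rng.choice(N, CONSENSUS_MAX_CELLS, replace=False))
        logger.info("consensus computed on a seeded subsample of %d cells", CONSENSUS_MAX_CELLS)
    else:
        subsample = None

    all_labels: dict[int, list[np.ndarray]] = {}
    consensus: dict[int, np.ndarray] = {}
    index: dict[int, float] = {}
    n_completed: dict[int, int] = {}
    for p in candidates:
        runs: list[np.ndarray] = []
        for b in range(1, B + 1):
            seed = base_seed + b
            try:
                res = fit(data, design, P=p, seed=seed, opts=opts)
                normU = normalize_embeddings(res.params.U)
                labels = cluster_cells(normU, k=cluster_k, resolution=resolution, seed=seed).labels
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("fit failed for P=%d run %d: %s", p, b, exc)
                continue
            runs.append(labels if subsample is None else labels[subsample])
        n_completed[p] = len(runs)
        if len(runs) < max(1, B // 2):
            logger.warning("candidate P=%d dropped: only %d/%d runs completed", p, len(runs), B)
            continue
        all_labels[p] = runs
        consensus[p] = consensus_matrix(runs)
        index[p] = consensus_index(runs)
    kept = [p for p in candidates if p in index]
    if not kept:
        raise RuntimeError("no candidate completed enough runs")
    selected = select_P(kept, [index[p] for p in kept])
    return ConsensusSummary(
        candidates=list(candidates),
        runs_per_candidate=B,
        labels=all_labels,
        consensus=consensus,
        index=index,
        selected=selected,
        n_completed=n_completed,
    )
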