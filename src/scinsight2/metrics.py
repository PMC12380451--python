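"""Evaluation metrics for integrated embeddings and clusterings.

Covers the covariate-specific integration index (local vs meso-scale
same-covariate neighbor frequency), the integration local inverse Simpson's
index (iLISI), adjusted Rand index, silhouette scores and the relative
contrast score used to pick representative metagenes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy
from sklearn.metrics import adjusted_rand_score, silhouette_samples
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("scinsight2")


@dataclass
class MetricReport:
    integration_index: dict[str, float] = field(default_factory=dict)
    ilisi: np.ndarray | None = None
    ilisi_median: float | None = None
    ari: float | None = None
    silhouette_values: np.ndarray | None = None
    silhouette_median: float | None = None
    contrast_scores: np.ndarray | None = None
    representative: np.ndarray | None = None
    top_metagenes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {"integration_index": self.integration_index}
        if self.ilisi_median is not None:
            out["ilisi_median"] = self.ilisi_median
        if self.ari is not None:
            out["ari"] = self.ari
        if self.silhouette_median is not None:
            out["silhouette_median"] = self.silhouette_median
        if self.contrast_scores is not None:
            out["contrast_scores"] = list(map(float, self.contrast_scores))
            out["representative_metagenes"] = self.top_metagenes
        return out


def _neighbor_order(embeddings: np.ndarray, chunk: int = 1024) -> np.ndarray:
    """All-pairs neighbor ordering, self excluded, distance ties broken by index.

    Returns an (N, N-1) array: row i lists the other cells by increasing
    Euclidean distance to cell i; equal distances are ordered by cell index
    (stable sort) for reproducibility.
    """
    X = np.atleast_2d(np.asarray(embeddings, dtype=float))
    N = X.shape[0]
    order = np.empty((N, N - 1), dtype=np.int64)
    sq = np.sum(X**2, axis=1)
    for i0 in range(0, N, chunk):
        i1 = min(i0 + chunk, N)
        d2 = sq[i0:i1, None] - 2.0 * (X[i0:i1] @ X.T) + sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        # round distances to break numeric jitter among exact geometric ties,
        # then stable-sort so remaining ties fall back to ascending index
        d2 = np.round(d2, 10)
        idx = np.argsort(d2, axis=1, kind="stable")
        for r, i in enumerate(range(i0, i1)):
            row = idx[r]
            order[i] = row[row != i][: N - 1]
    return order


def integration_index(
    embeddings: np.ndarray,
    covariate_values: np.ndarray,
    k1: int = 50,
    k2: int = 500,
) -> float:
    """Covariate-specific integration index in [0, 1].

    For each cell, compare the fraction of same-covariate-value cells among
    its k1 nearest neighbors with the fraction among its k2 nearest
    neighbors (self excluded); the index is the mean of 1 - |difference|.
    Values near 1 mean the covariate is as frequent locally as at meso scale,
    i.e. well integrated.
    """
    X = np.atleast_2d(np.asarray(embeddings, dtype=float))
    vals = np.asarray(covariate_values)
    N = X.shape[0]
    if len(vals) != N:
        raise ValueError("covariate values and embeddings disagree in length")
    if k1 >= k2:
        raise ValueError("k1 must be smaller than k2")
    if k2 > N - 1:
        logger.warning("k2=%d clamped to N-1=%d", k2, N - 1)
        k2 = N - 1
        if k1 >= k2:
            k1 = max(1, k2 - 1)
    order = _neighbor_order(X)
    same = vals[order] == vals[:, None]
    frac1 = same[:, :k1].mean(axis=1)
    frac2 = same[:, :k2].mean(axis=1)
    return float(np.mean(1.0 - np.abs(frac1 - frac2)))


def ilisi(
    embeddings: np.ndarray,
    sample_labels: np.ndarray,
    perplexity: float = 30.0,
) -> np.ndarray:
    """Per-cell integration LISI: inverse Simpson's index of sample mixing.

    Each cell's neighborhood is weighted by a Gaussian kernel whose bandwidth
    is tuned so the weight entropy matches log(perplexity); the score is the
    inverse Simpson's index of the resulting sample-membership probabilities.
    Ranges from 1 (fully segregated) to K, the number of samples.
    """
    X = np.atleast_2d(np.asarray(embeddings, dtype=float))
    labels = np.asarray(sample_labels)
    N = X.shape[0]
    if N < 2:
        raise ValueError("need at least 2 cells")
    if perplexity >= N:
        raise ValueError("perplexity must be below the number of cells")
    _, codes = np.unique(labels, return_inverse=True)
    K = codes.max() + 1
    k = min(N - 1, max(int(np.ceil(3 * perplexity)), 10))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    target = np.log(perplexity)
    scores = np.empty(N)
    for i in range(N):
        d2 = dist[i] ** 2
        lo, hi = 1e-10, 1e10
        beta = 1.0
        for _ in range(64):
            w = np.exp(-beta * d2)
            ws = w.sum()
            if ws <= 0:
                beta = lo = lo / 2
                continue
            p = w / ws
            h = -float(xlogy(p, p).sum())
            if abs(h - target) < 1e-5:
                break
            if h > target:
                lo = beta
            else:
                hi = beta
            beta = (lo + hi) / 2 if hi < 1e10 else beta * 2
        w = np.exp(-beta * d2)
        p = w / w.sum()
        probs = np.bincount(codes[idx[i]], weights=p, minlength=K)
        scores[i] = 1.0 / np.sum(probs**2)
    return np.clip(scores, 1.0, float(K))


def ari(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index between two partitions."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def silhouette(embeddings: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-cell silhouette scores (Euclidean), in [-1, 1]."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if np.all(counts == 1):
        raise ValueError("silhouette undefined for singleton-only labelings")
    return silhouette_samples(np.atleast_2d(embeddings), labels)


def relative_contrast(
    mean_expression: np.ndarray,
    threshold: float = 0.5,
    top_n: int = 4,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Relative contrast score per metagene over cluster-average expression.

    For each metagene, with t the top cluster's average expression and o the
    mean of the other clusters' averages, score = |t - o| / t (0 when t <= 0,
    with a warning).  Metagenes scoring above ``threshold`` are flagged
    representative; the indices of the ``top_n`` highest scorers are returned
    in descending score order.
    """
    A = np.atleast_2d(np.asarray(mean_expression, dtype=float))  # clusters x metagenes
    if A.shape[0] < 2:
        raise ValueError("need at least 2 clusters")
    t = A.max(axis=0)
    n_clusters = A.shape[0]
    o = (A.sum(axis=0) - t) / (n_clusters - 1)
    scores = np.zeros(A.shape[1])
    ok = t > 0
    if not ok.all():
        logger.warning("%d metagenes have non-positive top expression; scored 0", int((~ok).sum()))
    scores[ok] = np.abs(t[ok] - o[ok]) / t[ok]
    representative = scores > threshold
    order = np.argsort(-scores, kind="stable")
    top = [int(i) for i in order[:top_n]]
    return scores, representative, top
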