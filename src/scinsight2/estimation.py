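"""Approximate maximum-likelihood estimation of the Poisson GLLVM.

The marginal likelihood integrates the cell embeddings out of the Poisson
model; a Laplace approximation of that integral, with the asymptotically
dominated log-determinant term dropped, yields the tractable objective

    Q(Theta') = sum_ij (mu_ij - y_ij eta_ij)
              + sum_i ||u_i||^2 / (2 sigma^2) + N P log(sigma),

i.e. the negative Poisson log-likelihood (up to the y!-only additive
constant) plus a Gaussian shrinkage penalty on the embeddings.  Q is
minimized jointly over {beta0, B, Lambda, U} by a full-batch adaptive
first-order method (Adam-style moments) with sigma profiled out in closed
form each epoch, the loading constraint (upper-triangular leading block,
positive diagonal via a softplus reparameterization) enforced structurally,
and a monotonicity guard that rejects objective-increasing steps.

``laplace_marginal_loglik`` retains the per-cell inner-mode view of the
Laplace approximation *including* the dropped log-determinant term, as a
diagnostic against which the approximation quality can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .model_core import (
    ETA_CAP,
    SIGMA_FLOOR,
    DesignMatrix,
    ExpressionDataset,
    ModelParams,
)

logger = logging.getLogger("scinsight2")


# -- optimizer configuration --------------------------------------------------


@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit`.

    ``lr`` is the Adam step size; optimization stops when the relative change
    of Q over a ``stop_window``-epoch window falls below ``stop_tol`` or after
    ``max_epochs``.  ``monotone_slack`` is the relative increase of Q
    tolerated before a step is rejected (learning rate is then halved).
    """

    lr: float = 0.01
    max_epochs: int = 4000
    stop_tol: float = 1e-8
    stop_window: int = 10
    monotone_slack: float = 1e-8
    init_jitter_sd: float = 0.01
    eta_cap: float = ETA_CAP
    gene_block_size: int = 2048


@dataclass
class FitResult:
    params: ModelParams
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    seed: int
    settings: FitOptions = field(default_factory=FitOptions)


@dataclass
class LaplaceInternals:
    """Per-cell intermediates of the Laplace approximation."""

    u_tilde: np.ndarray
    W_tilde: np.ndarray  # diag of W at the mode, i.e. mu_tilde
    G_value: float
    logdet_term: float
    converged: bool = True


# -- loading-constraint handling ----------------------------------------------


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    # inverse of log(1+e^x); y must be positive
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


def constrain_loadings(raw: np.ndarray) -> np.ndarray:
    """Map an unconstrained P x M matrix onto the identifiability constraint.

    Entries below the diagonal of the leading P x P block are zeroed; diagonal
    entries pass through a softplus so they are strictly positive.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    P, M = raw.shape
    if P > M:
        raise ValueError("Lambda must have P <= M")
    out = raw.copy()
    mask = np.tril(np.ones((P, min(P, M))), k=-1).astype(bool)
    out[:, :P][mask] = 0.0
    d = np.arange(P)
    out[d, d] = _softplus(raw[d, d])
    return out


def _lambda_grad_chain(raw: np.ndarray, dLambda: np.ndarray) -> np.ndarray:
    """Chain rule through :func:`constrain_loadings` (structural zeros excluded)."""
    P, M = raw.shape
    g = dLambda.copy()
    mask = np.tril(np.ones((P, min(P, M))), k=-1).astype(bool)
    g[:, :P][mask] = 0.0
    d = np.arange(P)
    g[d, d] = dLambda[d, d] / (1.0 + np.exp(-raw[d, d]))  # sigmoid(raw)
    return g


# -- objective and gradients ---------------------------------------------------


def _as_parts(data: ExpressionDataset, design: DesignMatrix | np.ndarray):
    X = design.X if isinstance(design, DesignMatrix) else np.atleast_2d(design)
    s = np.asarray(data.size_factors, dtype=float)
    return data.counts, X, s


def _eta_block(params: ModelParams, X, logs, cols, eta_cap):
    eta = (
        params.beta0[None, cols]
        + logs[:, None]
        + X @ params.B[:, cols]
        + params.U @ params.Lambda[:, cols]
    )
    np.minimum(eta, eta_cap, out=eta)
    return eta


def objective(
    params: ModelParams,
    data: ExpressionDataset,
    design: DesignMatrix | np.ndarray,
    eta_cap: float = ETA_CAP,
    gene_block_size: int = 2048,
) -> float:
    """Q = sum(mu - y*eta) + sum ||u||^2/(2 sigma^2) + N P log sigma."""
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    Y, X, s = _as_parts(data, design)
    N, M = Y.shape
    logs = np.log(s)
    total = 0.0
    sparse = sp.issparse(Y)
    for j0 in range(0, M, gene_block_size):
        cols = slice(j0, min(j0 + gene_block_size, M))
        eta = _eta_block(params, X, logs, cols, eta_cap)
        Yb = np.asarray(Y[:, cols].todense()) if sparse else Y[:, cols]
        total += float(np.sum(np.exp(eta) - Yb * eta))
    P = params.P
    total += float(np.sum(params.U**2) / (2.0 * params.sigma**2))
    total += N * P * np.log(params.sigma)
    return total


def _objective_and_gradients(
    params: ModelParams,
    data: ExpressionDataset,
    design: DesignMatrix | np.ndarray,
    eta_cap: float = ETA_CAP,
    gene_block_size: int = 2048,
) -> tuple[float, dict[str, np.ndarray]]:
    """Single fused pass computing Q and all analytic gradient blocks."""
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    Y, X, s = _as_parts(data, design)
    N, M = Y.shape
    P = params.P
    logs = np.log(s)
    sparse = sp.issparse(Y)
    dbeta0 = np.zeros(M)
    dB = np.zeros_like(params.B)
    dLambda = np.zeros_like(params.Lambda)
    dU = np.zeros_like(params.U)
    total = 0.0
    for j0 in range(0, M, gene_block_size):
        cols = slice(j0, min(j0 + gene_block_size, M))
        eta = _eta_block(params, X, logs, cols, eta_cap)
        R = np.exp(eta)
        Yb = np.asarray(Y[:, cols].todense()) if sparse else Y[:, cols]
        total += float(np.sum(R - Yb * eta))
        R -= Yb
        dbeta0[cols] = R.sum(axis=0)
        dB[:, cols] = X.T @ R
        dLambda[:, cols] = params.U.T @ R
        dU += R @ params.Lambda[:, cols].T
    dU += params.U / params.sigma**2
    total += float(np.sum(params.U**2) / (2.0 * params.sigma**2))
    total += N * P * np.log(params.sigma)
    # zero the structurally fixed lower entries of the leading block
    mask = np.tril(np.ones((P, min(P, M))), k=-1).astype(bool)
    dLambda[:, :P][mask] = 0.0
    return total, {"beta0": dbeta0, "B": dB, "Lambda": dLambda, "U": dU}


def gradients(
    params: ModelParams,
    data: ExpressionDataset,
    design: DesignMatrix | np.ndarray,
    eta_cap: float = ETA_CAP,
    gene_block_size: int = 2048,
) -> dict[str, np.ndarray]:
    """Analytic gradient blocks of Q.

    With residual r_ij = mu_ij - y_ij:
      dQ/dbeta0_j    = sum_i r_ij
      dQ/dB[d, j]    = sum_i x_id r_ij
      dQ/dLambda[p,j] = sum_i u_ip r_ij   (masked to the free upper entries)
      dQ/du_i        = sum_j lambda_j r_ij + u_i / sigma^2
    """
    return _objective_and_gradients(params, data, design, eta_cap, gene_block_size)[1]


def update_sigma(U: np.ndarray, floor: float = SIGMA_FLOOR) -> float:
    """Closed-form minimizer of Q in sigma: sqrt(mean of squared embeddings)."""
    U = np.atleast_2d(U)
    return max(float(np.sqrt(np.mean(U**2))), floor)


# -- initialization ------------------------------------------------------------


def _initialize(
    data: ExpressionDataset,
    design: DesignMatrix | np.ndarray,
    P: int,
    rng: np.random.Generator,
    jitter_sd: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Warm start: covariate-only Poisson fit, then an SVD factor start on
    the log-ratio residuals.

    The intercepts and covariate coefficients are first estimated without any
    factors: OLS of log1p(y/s) on the design seeds (beta0, B), which a short
    Adam run on the factor-free Poisson likelihood then refines (the OLS
    seed alone under-corrects strong effects because of the log1p bias at low
    counts).  U and Lambda start from a rank-P truncated SVD of the log-ratio
    residuals log((y + 1/2) / (mu_hat + 1/2)) of that covariate-only model —
    starting the factors on covariate-adjusted residuals matters, since
    otherwise strong covariate effects dominate the top singular directions
    and the factors begin in a subspace describing the covariates rather than
    the cells.  Lambda's raw parameterization is projected so the constrained
    loadings match; a small seeded Gaussian jitter makes repeated
    initializations differ.
    """
    Y, X, s = _as_parts(data, design)
    N, M = Y.shape
    D = X.shape[1]
    Yd = np.asarray(Y.todense()) if sp.issparse(Y) else np.asarray(Y, dtype=float)
    logs = np.log(s)
    Z = np.log1p(Yd / s[:, None])
    if D:
        Xa = np.column_stack([np.ones(N), X])
        coef, *_ = np.linalg.lstsq(Xa, Z, rcond=None)
        beta0, B0 = coef[0].copy(), coef[1:].copy()
    else:
        beta0 = np.log(np.maximum(Yd.sum(axis=0), 1e-8) / s.sum())
        B0 = np.zeros((0, M))
    # short factor-free Poisson refinement of (beta0, B)
    adam = _Adam({"beta0": beta0.shape, "B": B0.shape}, lr=0.05)
    for _ in range(300):
        mu = np.exp(np.minimum(beta0[None, :] + logs[:, None] + X @ B0, ETA_CAP))
        R = mu - Yd
        steps = adam.step({"beta0": R.sum(axis=0), "B": X.T @ R})
        beta0 -= steps["beta0"]
        B0 -= steps["B"]
    mu = np.exp(np.minimum(beta0[None, :] + logs[:, None] + X @ B0, ETA_CAP))
    Z = np.log((Yd + 0.5) / (mu + 0.5))
    # rank-P truncated SVD (deterministic)
    try:
        from scipy.sparse.linalg import svds

        k = min(P, min(N, M) - 1)
        Usv, sv, Vt = svds(Z, k=k, random_state=0)
        order = np.argsort(-sv)
        Usv, sv, Vt = Usv[:, order], sv[order], Vt[order]
    except Exception:  # tiny problems: dense fallback
        Usv, sv, Vt = np.linalg.svd(Z, full_matrices=False)
        Usv, sv, Vt = Usv[:, :P], sv[:P], Vt[:P]
    k = len(sv)
    scale = np.sqrt(np.maximum(sv, 1e-6))
    U0 = np.zeros((N, P))
    L0 = np.zeros((P, M))
    U0[:, :k] = Usv * scale[None, :]
    L0[:k, :] = scale[:, None] * Vt
    # raw (unconstrained) loading parameterization reproducing |L0| on the diagonal
    raw = L0.copy()
    d = np.arange(min(P, M))
    raw[d, d] = _softplus_inv(np.maximum(np.abs(L0[d, d]), 0.05))
    U0 = U0 + rng.normal(0.0, jitter_sd, size=U0.shape)
    raw = raw + rng.normal(0.0, jitter_sd, size=raw.shape)
    return beta0, B0, raw, U0


# -- the optimizer loop --------------------------------------------------------


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(sh) for k, sh in shapes.items()}
        self.v = {k: np.zeros(sh) for k, sh in shapes.items()}
        self.t = 0

    def step(self, grads):
        self.t += 1
        out = {}
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            out[k] = self.lr * mh / (np.sqrt(vh) + self.eps)
        return out


def fit(
    data: ExpressionDataset,
    design: DesignMatrix | np.ndarray,
    P: int,
    seed: int = 0,
    opts: FitOptions | None = None,
) -> FitResult:
    """Fit the GLLVM by minimizing Q with the loading constraint enforced.

    Deterministic for a fixed seed: the seed only controls the Gaussian
    jitter added to the SVD warm start.  The recorded objective trace is
    monotone non-increasing up to ``opts.monotone_slack`` relative slack.
    """
    opts = opts or FitOptions()
    if P < 1:
        raise ValueError("P must be >= 1")
    if data.n_cells == 0 or data.n_genes == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    beta0, B, raw, U = _initialize(data, design, P, rng, opts.init_jitter_sd)
    sigma = update_sigma(U)

    def pack() -> ModelParams:
        return ModelParams(beta0=beta0, B=B, Lambda=constrain_loadings(raw), sigma=sigma, U=U)

    params = pack()
    Q, g = _objective_and_gradients(params, data, design, opts.eta_cap, opts.gene_block_size)
    if not np.isfinite(Q):
        raise ValueError(
            "objective non-finite at initialization; check counts/size factors or lower eta_cap"
        )
    trace = [Q]
    shapes = {"beta0": beta0.shape, "B": B.shape, "Lambda": raw.shape, "U": U.shape}
    adam = _Adam(shapes, opts.lr)
    lr_scale = 1.0
    converged = False
    epoch = 0
    for epoch in range(1, opts.max_epochs + 1):
        g_step = dict(g)
        g_step["Lambda"] = _lambda_grad_chain(raw, g["Lambda"])
        steps = adam.step(g_step)
        new_beta0 = beta0 - lr_scale * steps["beta0"]
        new_B = B - lr_scale * steps["B"]
        new_raw = raw - lr_scale * steps["Lambda"]
        new_U = U - lr_scale * steps["U"]
        new_sigma = update_sigma(new_U)
        cand = ModelParams(
            beta0=new_beta0, B=new_B, Lambda=constrain_loadings(new_raw), sigma=new_sigma, U=new_U
        )
        Q_new, g_new = _objective_and_gradients(
            cand, data, design, opts.eta_cap, opts.gene_block_size
        )
        if not np.isfinite(Q_new) or Q_new > Q + opts.monotone_slack * abs(Q):
            # rejected step: halve the effective learning rate and retry next epoch
            lr_scale *= 0.5
            if lr_scale < 1e-8:
                logger.warning("step size collapsed at epoch %d; stopping", epoch)
                break
            continue
        beta0, B, raw, U, sigma = new_beta0, new_B, new_raw, new_U, new_sigma
        params = cand
        Q, g = Q_new, g_new
        trace.append(Q)
        w = opts.stop_window
        if len(trace) > w:
            prev = trace[-w - 1]
            rel = abs(prev - Q) / max(abs(prev), 1.0)
            if rel < opts.stop_tol:
                converged = True
                break
    return FitResult(
        params=params,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=epoch,
        seed=seed,
        settings=opts,
    )


# -- Laplace diagnostic --------------------------------------------------------


def laplace_marginal_loglik(
    params: ModelParams,
    cell_counts: np.ndarray,
    x: np.ndarray,
    s: float,
    max_newton: int = 100,
    tol: float = 1e-10,
) -> tuple[float, LaplaceInternals]:
    """Full Laplace approximation of one cell's marginal log-likelihood.

    Approximates log integral over u of prod_j Poisson(y_j; mu_j(u)) times the
    N(0, sigma^2 I_P) prior, excluding the y!-only additive constant.  Unlike
    the training objective, the log-determinant curvature term is *included*
    and exposed separately so its magnitude can be audited:

        l approx = sum_j (y_j eta~_j - mu~_j) - ||u~||^2/(2 sigma^2)
                 - P log(sigma) - 1/2 log|Lambda W~ Lambda' + sigma^-2 I_P|

    where u~ is the inner mode found by Newton's method.
    """
    y = np.asarray(cell_counts, dtype=float)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    L = params.Lambda
    P, M = L.shape
    base = params.beta0 + np.log(s) + x @ params.B  # (M,)
    sig2 = params.sigma**2

    def eta_of(u):
        return base + u @ L

    u = np.zeros(P)
    converged = False
    for _ in range(max_newton):
        mu = np.exp(eta_of(u))
        grad = -L @ (y - mu) + u / sig2  # dG/du
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        H = (L * mu[None, :]) @ L.T + np.eye(P) / sig2
        u = u - np.linalg.solve(H, grad)
    else:
        mu = np.exp(eta_of(u))
        grad = -L @ (y - mu) + u / sig2
        converged = bool(np.linalg.norm(grad) < 1e-6)
        if not converged:
            logger.warning("inner Newton solve did not converge (|grad|=%.2e)", np.linalg.norm(grad))

    eta_t = eta_of(u)
    mu_t = np.exp(eta_t)
    H = (L * mu_t[None, :]) @ L.T + np.eye(P) / sig2
    sign, logdet = np.linalg.slogdet(H)
    logdet_term = -0.5 * logdet
    fit_term = float(np.sum(y * eta_t - mu_t))
    G_value = -fit_term + float(u @ u) / (2 * sig2) + P * np.log(params.sigma)
    approx = fit_term - float(u @ u) / (2 * sig2) - P * np.log(params.sigma) + logdet_term
    internals = LaplaceInternals(
        u_tilde=u, W_tilde=mu_t, G_value=G_value, logdet_term=logdet_term, converged=converged
    )
    return approx, internals
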