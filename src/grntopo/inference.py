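"""Network inference: from expression matrix to signed coupling network J.

The maximum-entropy pairwise model for continuous expression levels that
matches the observed first and second moments is the multivariate Gaussian
P(S) = exp(-(S - <S>)' C^{-1} (S - <S>) / 2) / ((2 pi)^{L/2} det(C)^{1/2}),
so the couplings are read off the precision matrix: J_ij = -(C^{-1})_ij for
i != j. Because the empirical inverse covariance is dense, the precision
matrix is estimated by the graphical lasso — the l1-penalized Gaussian
maximum-likelihood estimator — implemented here from scratch as block
coordinate descent (one lasso regression per row/column, diagonal
unpenalized), with a numba-compiled inner loop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import linalg

from .containers import CovarianceModel, ExpressionMatrix, InteractionNetwork

__all__ = [
    "GraphicalLassoResult",
    "ConvergenceError",
    "rpkm_normalize",
    "select_top_variance_genes",
    "estimate_covariance",
    "graphical_lasso",
    "glasso_objective",
    "glasso_kkt_gap",
    "interactions_from_precision",
    "model_log_density",
    "select_penalty",
    "infer_network",
]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the graphical lasso does not converge within max_iter."""


def rpkm_normalize(
    counts: np.ndarray,
    gene_lengths: np.ndarray,
    gene_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """Reads Per Kilobase transcript per Million reads.

    value(g, s) = 1e9 * count(g, s) / (length_bp(g) * column_sum(s)),
    normalizing jointly for library size (column sums) and gene length.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if counts.ndim != 2 or lengths.shape != (counts.shape[0],):
        raise ValueError("gene_lengths must align with count-matrix rows")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    libsize = counts.sum(axis=0)
    if np.any(libsize <= 0):
        raise ValueError("every sample must have a positive library size")
    values = 1e9 * counts / (lengths[:, None] * libsize[None, :])
    n_genes, n_samples = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    if sample_ids is None:
        sample_ids = [f"s{j:05d}" for j in range(n_samples)]
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)


def select_top_variance_genes(expr: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the k genes of largest per-gene expression variance.

    Output rows are ordered by descending variance; ties keep input order.
    Genes with zero variance are never selectable.
    """
    if k < 1:
        raise ValueError("k must be positive")
    var = expr.values.var(axis=1)
    positive = int(np.count_nonzero(var > 0))
    if k > positive:
        raise ValueError(
            f"requested {k} genes but only {positive} have strictly positive variance"
        )
    order = np.argsort(-var, kind="stable")[:k]
    return ExpressionMatrix(
        gene_ids=[expr.gene_ids[i] for i in order],
        sample_ids=list(expr.sample_ids),
        values=expr.values[order],
    )


def estimate_covariance(
    expr: ExpressionMatrix, drop_constant: bool = True
) -> CovarianceModel:
    """Per-gene means and the maximum-likelihood (divisor n) covariance.

    Zero-variance genes are dropped with a logged warning when
    ``drop_constant`` is set (they make the covariance singular); otherwise
    their presence is an error.
    """
    if expr.n_samples < 2:
        raise ValueError("covariance estimation requires at least 2 samples")
    var = expr.values.var(axis=1)
    keep = var > 0
    if not np.all(keep):
        bad = [expr.gene_ids[i] for i in np.nonzero(~keep)[0]]
        if not drop_constant:
            raise ValueError(f"constant genes present: {bad}")
        warnings.warn(f"dropping {len(bad)} zero-variance genes: {bad}", stacklevel=2)
        logger.warning("dropping zero-variance genes: %s", bad)
    values = expr.values[keep]
    gene_ids = [g for g, k_ in zip(expr.gene_ids, keep) if k_]
    mean = values.mean(axis=1)
    centered = values - mean[:, None]
    cov = centered @ centered.T / expr.n_samples
    return CovarianceModel(
        gene_ids=gene_ids, mean=mean, covariance=cov, n_samples_used=expr.n_samples
    )


# ---------------------------------------------------------------------------
# Graphical lasso
# ---------------------------------------------------------------------------


@njit(cache=False)
def _lasso_cd(W11, s12, lam, beta, tol, max_iter):  # pragma: no cover - numba
    """Cyclic coordinate descent for min 0.5 b'W11 b - s12'b + lam*|b|_1."""
    p = s12.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for i in range(p):
            old = beta[i]
            r = s12[i]
            for m in range(p):
                r -= W11[i, m] * beta[m]
            r += W11[i, i] * old
            if r > lam:
                new = (r - lam) / W11[i, i]
            elif r < -lam:
                new = (r + lam) / W11[i, i]
            else:
                new = 0.0
            delta = abs(new - old)
            if delta > dmax:
                dmax = delta
            beta[i] = new
        if dmax < tol:
            break
    return beta


@dataclass
class GraphicalLassoResult:
    """Solution of the l1-penalized precision estimation problem."""

    precision: np.ndarray
    covariance: np.ndarray  # the dual estimate W ~= precision^{-1}
    penalty: float
    n_iter: int
    converged: bool


def graphical_lasso(
    S: np.ndarray,
    penalty: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    inner_tol: float | None = None,
    inner_max_iter: int = 5000,
    raise_on_nonconvergence: bool = True,
) -> GraphicalLassoResult:
    """Sparse precision matrix by block coordinate descent (from scratch).

    Minimizes -log det(Theta) + tr(S Theta) + penalty * sum_{i!=j} |Theta_ij|
    (diagonal unpenalized). Each outer sweep solves one lasso subproblem per
    column against the current working covariance W; at optimality the KKT
    conditions hold: diag(Theta^{-1}) = diag(S) and
    |(Theta^{-1} - S)_ij| <= penalty off the diagonal, with equality (signed)
    on the active set.

    Convergence: max absolute change of Theta relative to its magnitude below
    ``tol``. Non-convergence raises :class:`ConvergenceError` carrying the
    final gap unless ``raise_on_nonconvergence`` is false.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be a symmetric square matrix")
    if np.any(np.diag(S) <= 0):
        raise ValueError("S must have a strictly positive diagonal")
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    if p == 1:
        Theta = np.array([[1.0 / S[0, 0]]])
        return GraphicalLassoResult(Theta, S.copy(), penalty, 0, True)
    if inner_tol is None:
        inner_tol = min(tol * 0.1, 1e-8)

    W = S.copy()
    B = np.zeros((p, p))  # B[rest, j] holds the lasso coefficients of column j
    rest_idx = [np.array([m for m in range(p) if m != j]) for j in range(p)]

    def reconstruct() -> np.ndarray:
        Theta = np.empty((p, p))
        for j in range(p):
            rest = rest_idx[j]
            beta = B[rest, j]
            theta_jj = 1.0 / (S[j, j] - W[rest, j] @ beta)
            Theta[j, j] = theta_jj
            Theta[rest, j] = -beta * theta_jj
        return (Theta + Theta.T) / 2

    Theta = reconstruct()
    converged = False
    n_iter = 0
    change = np.inf
    for n_iter in range(1, max_iter + 1):
        for j in range(p):
            rest = rest_idx[j]
            W11 = np.ascontiguousarray(W[np.ix_(rest, rest)])
            beta = np.ascontiguousarray(B[rest, j])
            _lasso_cd(W11, S[rest, j].copy(), penalty, beta, inner_tol, inner_max_iter)
            B[rest, j] = beta
            w12 = W11 @ beta
            W[rest, j] = w12
            W[j, rest] = w12
        Theta_new = reconstruct()
        scale = max(np.abs(Theta).max(), 1e-12)
        change = np.abs(Theta_new - Theta).max() / scale
        Theta = Theta_new
        if change < tol:
            converged = True
            break
    if not converged and raise_on_nonconvergence:
        raise ConvergenceError(
            f"graphical lasso did not converge in {max_iter} sweeps "
            f"(final relative change {change:.3e})"
        )
    return GraphicalLassoResult(Theta, W, penalty, n_iter, converged)


def glasso_objective(Theta: np.ndarray, S: np.ndarray, penalty: float) -> float:
    """-log det(Theta) + tr(S Theta) + penalty * l1 norm of the off-diagonal."""
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        return np.inf
    off = np.abs(Theta).sum() - np.abs(np.diag(Theta)).sum()
    return float(-logdet + np.trace(S @ Theta) + penalty * off)


def glasso_kkt_gap(Theta: np.ndarray, S: np.ndarray, penalty: float) -> float:
    """Maximum violation of the stationarity conditions of the glasso problem.

    Zero at the optimum: diag(W - S) = 0, (W - S)_ij = penalty * sign(Theta_ij)
    on active off-diagonals, |(W - S)_ij| <= penalty elsewhere, W = Theta^{-1}.
    """
    W = linalg.inv(Theta)
    R = W - S
    gap = float(np.abs(np.diag(R)).max())
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    active = off & (Theta != 0)
    inactive = off & (Theta == 0)
    if active.any():
        gap = max(gap, float(np.abs(R[active] - penalty * np.sign(Theta[active])).max()))
    if inactive.any():
        gap = max(gap, float(np.maximum(np.abs(R[inactive]) - penalty, 0.0).max()))
    return gap


def interactions_from_precision(
    Theta: np.ndarray, gene_ids: list[str], meta: dict | None = None
) -> InteractionNetwork:
    """Couplings from the precision matrix: J_ij = -Theta_ij, zero diagonal."""
    Theta = np.asarray(Theta, dtype=float)
    if Theta.shape != (len(gene_ids), len(gene_ids)):
        raise ValueError("precision dimension does not match gene_ids")
    if not np.allclose(Theta, Theta.T, atol=1e-10):
        raise ValueError("precision must be symmetric")
    J = -(Theta + Theta.T) / 2
    np.fill_diagonal(J, 0.0)
    return InteractionNetwork(gene_ids=list(gene_ids), weights=J, meta=meta or {})


def model_log_density(model: CovarianceModel, s: np.ndarray) -> float:
    """Log density of the maximum-entropy Gaussian at expression vector s."""
    s = np.asarray(s, dtype=float)
    if s.shape != (model.n_genes,):
        raise ValueError("vector dimension does not match model")
    C = model.covariance
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        raise ValueError("covariance is singular or not positive definite")
    d = s - model.mean
    quad = d @ np.linalg.solve(C, d)
    L = model.n_genes
    return float(-0.5 * quad - 0.5 * L * np.log(2 * np.pi) - 0.5 * logdet)


def select_penalty(
    expr: ExpressionMatrix,
    grid: np.ndarray | None = None,
    train_fraction: float = 0.75,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> float:
    """Penalty heuristic: maximize held-out Gaussian log-likelihood.

    Samples are split once into train/validation; for each penalty on a
    log-spaced grid the precision is fit on the training covariance and scored
    by log det(Theta) - tr(S_val Theta) on the validation covariance.
    """
    if grid is None:
        grid = np.logspace(-3, 0, 10)
    rng = np.random.default_rng(seed)
    n = expr.n_samples
    perm = rng.permutation(n)
    n_train = max(2, int(round(train_fraction * n)))
    n_train = min(n_train, n - 2)
    tr, va = perm[:n_train], perm[n_train:]

    def cov_of(cols: np.ndarray) -> np.ndarray:
        v = expr.values[:, cols]
        c = v - v.mean(axis=1, keepdims=True)
        return c @ c.T / cols.size

    S_tr, S_va = cov_of(tr), cov_of(va)
    best_pen, best_score = float(grid[0]), -np.inf
    for pen in grid:
        try:
            res = graphical_lasso(
                S_tr, float(pen), tol=tol, max_iter=max_iter,
                raise_on_nonconvergence=False,
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        sign, logdet = np.linalg.slogdet(res.precision)
        if sign <= 0:
            continue
        score = logdet - np.trace(S_va @ res.precision)
        if score > best_score:
            best_score, best_pen = float(score), float(pen)
    return best_pen


def infer_network(
    expr: ExpressionMatrix,
    penalty: float,
    top_k: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    use_correlation: bool = False,
) -> InteractionNetwork:
    """Full inference chain: variance filter -> moments -> glasso -> J.

    ``use_correlation`` feeds the unit-diagonal correlation matrix to the
    graphical lasso instead of the covariance.
    """
    if top_k is not None:
        expr = select_top_variance_genes(expr, top_k)
    model = estimate_covariance(expr)
    S = model.covariance
    if use_correlation:
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
    res = graphical_lasso(S, penalty, tol=tol, max_iter=max_iter)
    meta = {
        "penalty": penalty,
        "tol": tol,
        "n_samples": model.n_samples_used,
        "n_genes": model.n_genes,
        "n_iter": res.n_iter,
        "input": "correlation" if use_correlation else "covariance",
    }
    return interactions_from_precision(res.precision, model.gene_ids, meta=meta)
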