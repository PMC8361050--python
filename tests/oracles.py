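"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a different route from the package
implementation it checks: exhaustive enumeration for triads and squares,
an ADMM proximal-splitting solver for the graphical-lasso objective, and
elementwise brute-force formulas for RPKM and covariance.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_triads(W: np.ndarray) -> list[tuple[tuple[int, int, int], float]]:
    """Triple loop over all node triples; keep closed triangles."""
    n = W.shape[0]
    out = []
    for i, j, k in combinations(range(n), 3):
        if W[i, j] != 0 and W[j, k] != 0 and W[k, i] != 0:
            out.append(((i, j, k), W[i, j] * W[j, k] * W[k, i]))
    return out


def brute_force_square_count(W: np.ndarray) -> float:
    """Exhaustive sum of Delta_a * Delta_b over all unordered pairs of
    distinct triangles sharing a common edge (Delta = sign of the product)."""
    tris = brute_force_triads(W)
    s = 0.0
    for a in range(len(tris)):
        for b in range(a + 1, len(tris)):
            (na, ea), (nb, eb) = tris[a], tris[b]
            shared = set(na) & set(nb)
            if len(shared) == 2:
                s += np.sign(ea) * np.sign(eb)
    return s


def brute_force_cliques(W: np.ndarray, max_size: int) -> dict[tuple[int, ...], float]:
    """All cliques up to max_size vertices with max-edge filtration values,
    by exhaustive subset enumeration on |W|."""
    n = W.shape[0]
    out: dict[tuple[int, ...], float] = {}
    for i in range(n):
        out[(i,)] = 0.0
    for size in range(2, max_size + 1):
        for verts in combinations(range(n), size):
            pairs = list(combinations(verts, 2))
            if all(W[a, b] != 0 for a, b in pairs):
                out[verts] = max(abs(W[a, b]) for a, b in pairs)
    return out


def admm_graphical_lasso(
    S: np.ndarray, lam: float, rho: float = 1.0, iters: int = 50000, tol: float = 1e-12
) -> np.ndarray:
    """Graphical lasso by ADMM splitting (diagonal unpenalized).

    Alternates a log-det proximal step (eigendecomposition) with soft
    thresholding; independent of the coordinate-descent implementation.
    """
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(iters):
        w, V = np.linalg.eigh(rho * (Z - U) - S)
        ev = (w + np.sqrt(w**2 + 4 * rho)) / (2 * rho)
        Theta = (V * ev) @ V.T
        Z_old = Z
        X = Theta + U
        Z = np.sign(X) * np.maximum(np.abs(X) - lam / rho, 0.0)
        np.fill_diagonal(Z, np.diag(X))
        U = U + Theta - Z
        primal = np.linalg.norm(Theta - Z)
        dual = rho * np.linalg.norm(Z - Z_old)
        if primal < tol and dual < tol:
            break
    return Z


def random_spd(p: int, rng: np.random.Generator, cond_boost: float = 0.3) -> np.ndarray:
    A = rng.standard_normal((p, p))
    return A @ A.T / p + np.eye(p) * cond_boost


def random_signed_weights(
    n: int, density: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric signed weight matrix with zero diagonal."""
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < density
    vals = rng.uniform(0.05, 1.0, size=iu.size) * np.where(
        rng.random(iu.size) < 0.5, -1.0, 1.0
    )
    W[iu[mask], ju[mask]] = vals[mask]
    return W + W.T
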