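"""Synthetic ground truth: sparse precision matrices, Gaussian expression
cohorts, and small toy networks with known homology.

The generators emulate the study design of the inference pipeline: expression
is multivariate Gaussian with a known sparse signed precision matrix Theta, so
that the true coupling network J = -Theta (off-diagonal) is available for
recovery experiments. Cohort pairs share a support/sign pattern but differ in
the width of the interaction-weight distribution (narrow "cancer-like" vs
broad "normal-like"), isolating weight spread as the only contrast. Toy
networks (cycles, complete graphs, the octahedron, and composites) provide
fixtures whose Betti numbers are known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .containers import ExpressionMatrix, InteractionNetwork

__all__ = [
    "PrecisionSpec",
    "SyntheticCohort",
    "generate_sparse_precision",
    "sample_expression",
    "generate_toy_network",
    "toy_network_names",
    "generate_cohort_pair",
]


@dataclass(frozen=True)
class PrecisionSpec:
    """Parameters of a random sparse symmetric-positive-definite precision matrix.

    Off-diagonal support is Bernoulli(edge_density); magnitudes are uniform in
    [weight_low, weight_high]; signs are negative with probability
    negative_fraction. Diagonals are set to the row absolute sum plus
    diagonal_boost, making the matrix strictly diagonally dominant and hence SPD.
    """

    n_genes: int
    edge_density: float
    weight_low: float = 0.1
    weight_high: float = 0.5
    negative_fraction: float = 0.5
    diagonal_boost: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be at least 2")
        if not 0 < self.edge_density < 1:
            raise ValueError("edge_density must lie strictly in (0, 1)")
        if not 0 < self.weight_low <= self.weight_high:
            raise ValueError("need 0 < weight_low <= weight_high")
        if not 0 <= self.negative_fraction <= 1:
            raise ValueError("negative_fraction must lie in [0, 1]")
        if self.diagonal_boost <= 0:
            raise ValueError("diagonal_boost must be positive")


@dataclass
class SyntheticCohort:
    """A simulated expression cohort with its generating precision matrix."""

    expression: ExpressionMatrix
    true_precision: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.expression.n_genes != self.true_precision.shape[0]:
            raise ValueError("expression gene count does not match precision dimension")

    def true_network(self) -> InteractionNetwork:
        """Ground-truth coupling network J = -Theta off-diagonal."""
        J = -self.true_precision.copy()
        np.fill_diagonal(J, 0.0)
        return InteractionNetwork(gene_ids=list(self.expression.gene_ids), weights=J)


def generate_sparse_precision(spec: PrecisionSpec) -> np.ndarray:
    """Draw a random sparse SPD precision matrix according to ``spec``.

    Deterministic for a fixed spec (including seed). Strict diagonal dominance
    guarantees all eigenvalues are at least ``diagonal_boost`` > 0.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_genes
    iu, ju = np.triu_indices(p, k=1)
    support = rng.random(iu.size) < spec.edge_density
    mags = rng.uniform(spec.weight_low, spec.weight_high, size=iu.size)
    signs = np.where(rng.random(iu.size) < spec.negative_fraction, -1.0, 1.0)
    vals = np.where(support, mags * signs, 0.0)

    Theta = np.zeros((p, p))
    Theta[iu, ju] = vals
    Theta += Theta.T
    np.fill_diagonal(Theta, np.abs(Theta).sum(axis=1) + spec.diagonal_boost)
    return Theta


def _cholesky_or_raise(matrix: np.ndarray, what: str) -> np.ndarray:
    try:
        return linalg.cholesky(matrix, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"{what} is not symmetric positive definite") from exc


def sample_expression(
    precision: np.ndarray,
    n_samples: int,
    mean: np.ndarray | None = None,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """Sample a genes x samples expression matrix from the Gaussian with
    covariance equal to the inverse of ``precision``.

    Means default to zero: the downstream analysis depends only on second
    moments, so location carries no information.
    """
    precision = np.asarray(precision, dtype=float)
    p = precision.shape[0]
    if precision.shape != (p, p) or not np.allclose(precision, precision.T, atol=1e-10):
        raise ValueError("precision must be a symmetric square matrix")
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    _cholesky_or_raise(precision, "precision")
    cov = linalg.inv(precision)
    cov = (cov + cov.T) / 2
    chol = _cholesky_or_raise(cov, "covariance")
    mu = np.zeros(p) if mean is None else np.asarray(mean, dtype=float)
    if mu.shape != (p,):
        raise ValueError("mean dimension does not match precision")

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((p, n_samples))
    values = chol @ z + mu[:, None]
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(p)]
    sample_ids = [f"s{j:05d}" for j in range(n_samples)]
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)


# ---------------------------------------------------------------------------
# Toy networks with known homology
# ---------------------------------------------------------------------------


def _net_from_edges(n: int, edges: list[tuple[int, int, float]]) -> InteractionNetwork:
    W = np.zeros((n, n))
    for i, j, w in edges:
        W[i, j] = W[j, i] = w
    return InteractionNetwork(gene_ids=[f"v{i}" for i in range(n)], weights=W)


def _cycle(n: int) -> InteractionNetwork:
    if n < 3:
        raise ValueError("cycle needs at least 3 nodes")
    return _net_from_edges(n, [(i, (i + 1) % n, 1.0) for i in range(n)])


def _complete(n: int) -> InteractionNetwork:
    if n < 2:
        raise ValueError("complete graph needs at least 2 nodes")
    return _net_from_edges(n, [(i, j, 1.0) for i in range(n) for j in range(i + 1, n)])


def _octahedron() -> InteractionNetwork:
    # K_{2,2,2}: all pairs except the three antipodal ones. Every node has
    # degree 4; the clique complex is a triangulated 2-sphere (one void).
    antipodal = {(0, 1), (2, 3), (4, 5)}
    edges = [
        (i, j, 1.0)
        for i in range(6)
        for j in range(i + 1, 6)
        if (i, j) not in antipodal
    ]
    return _net_from_edges(6, edges)


def _fig1c_analog() -> InteractionNetwork:
    # Octahedron (one 2-hole) with two edge-disjoint pendant 4-cycles attached
    # at vertex 0 (two 1-holes); connected, all unit weights.
    # Betti vector of the full clique complex: (1, 2, 1).
    base = _octahedron()
    edges = [(i, j, w) for i, j, w in base.edges()]
    edges += [(0, 6, 1.0), (6, 7, 1.0), (7, 8, 1.0), (8, 0, 1.0)]
    edges += [(0, 9, 1.0), (9, 10, 1.0), (10, 11, 1.0), (11, 0, 1.0)]
    return _net_from_edges(12, edges)


def _fig2_analog() -> InteractionNetwork:
    # Small weighted network with distinct edge weights: a 4-cycle (1-hole born
    # at 0.4) closed by a chord at 0.8 (both flanking triangles enter with the
    # chord, killing the hole), plus a pendant vertex. Produces finite bars in
    # dimensions 0 and 1.
    edges = [
        (0, 1, 0.1),
        (1, 2, 0.2),
        (2, 3, 0.3),
        (3, 0, 0.4),
        (1, 4, 0.6),
        (0, 2, 0.8),
    ]
    return _net_from_edges(5, edges)


_FIXED_TOYS = {
    "octahedron": _octahedron,
    "fig1c_analog": _fig1c_analog,
    "fig2_analog": _fig2_analog,
}


def toy_network_names() -> list[str]:
    """Registered fixture names (parametric families shown with ``_n``)."""
    return sorted(_FIXED_TOYS) + ["cycle_n", "complete_n"]


def generate_toy_network(name: str) -> InteractionNetwork:
    """Return a deterministic small weighted network by registry name.

    Parametric families: ``cycle_<n>`` (n-cycle, unit weights) and
    ``complete_<n>`` (K_n, unit weights). Fixed fixtures: ``octahedron``,
    ``fig1c_analog``, ``fig2_analog``.
    """
    if name in _FIXED_TOYS:
        return _FIXED_TOYS[name]()
    for prefix, builder in (("cycle_", _cycle), ("complete_", _complete)):
        if name.startswith(prefix):
            try:
                n = int(name[len(prefix):])
            except ValueError:
                raise KeyError(f"unknown toy network {name!r}") from None
            return builder(n)
    raise KeyError(f"unknown toy network {name!r}")


# ---------------------------------------------------------------------------
# Cohort pairs contrasting weight-distribution width
# ---------------------------------------------------------------------------


def generate_cohort_pair(
    n_genes: int = 50,
    n_samples_a: int = 2000,
    n_samples_b: int = 2000,
    width_a: tuple[float, float] = (0.1, 0.2),
    width_b: tuple[float, float] = (0.1, 0.8),
    edge_density: float = 0.1,
    negative_fraction: float = 0.5,
    diagonal_boost: float = 1.0,
    seed: int = 0,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Generate two cohorts sharing a support/sign pattern whose coupling
    magnitudes are drawn from intervals of different widths.

    The cohort with the narrower magnitude interval is labelled
    ``"cancer-like"`` and the broader one ``"normal-like"``; with equal widths
    both are labelled ``"matched"``. Support and signs are drawn once from the
    seed, so weight spread is the only systematic contrast.
    """
    for counts in (n_genes, n_samples_a, n_samples_b):
        if counts < 1:
            raise ValueError("all counts must be positive")
    for lo, hi in (width_a, width_b):
        if not 0 < lo <= hi:
            raise ValueError("width intervals must satisfy 0 < low <= high")

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_genes, k=1)
    support = rng.random(iu.size) < edge_density
    signs = np.where(rng.random(iu.size) < negative_fraction, -1.0, 1.0)
    u = rng.random(iu.size)  # shared quantile draw -> comonotone magnitudes

    def build(width: tuple[float, float]) -> np.ndarray:
        lo, hi = width
        vals = np.where(support, (lo + u * (hi - lo)) * signs, 0.0)
        Theta = np.zeros((n_genes, n_genes))
        Theta[iu, ju] = vals
        Theta += Theta.T
        np.fill_diagonal(Theta, np.abs(Theta).sum(axis=1) + diagonal_boost)
        return Theta

    span_a, span_b = width_a[1] - width_a[0], width_b[1] - width_b[0]
    if span_a == span_b:
        label_a = label_b = "matched"
    elif span_a < span_b:
        label_a, label_b = "cancer-like", "normal-like"
    else:
        label_a, label_b = "normal-like", "cancer-like"

    theta_a = build(width_a)
    theta_b = build(width_b)
    seed_a = int(rng.integers(2**31 - 1))
    seed_b = int(rng.integers(2**31 - 1))
    cohort_a = SyntheticCohort(
        expression=sample_expression(theta_a, n_samples_a, seed=seed_a),
        true_precision=theta_a,
        label=label_a,
    )
    cohort_b = SyntheticCohort(
        expression=sample_expression(theta_b, n_samples_b, seed=seed_b),
        true_precision=theta_b,
        label=label_b,
    )
    return cohort_a, cohort_b
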