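"""Persistent homology of weighted clique (flag) complexes over Z2.

The weighted network is turned into a sublevel filtration: vertices enter at
weight 0, an edge at its (absolute) weight, and every higher simplex at the
maximum of its edges' weights, so the complex at threshold w is the clique
complex of the graph restricted to edges of weight <= w. Persistence is
computed by the standard boundary-matrix column reduction over Z2; a
rank-based brute-force computation of static Betti numbers serves as an
independent oracle for small instances.

Betti numbers beta_0, beta_1, beta_2 count connected components, loops and
voids; a class that never dies (death = +inf) is an essential class of the
full complex.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .containers import InteractionNetwork

__all__ = [
    "Simplex",
    "Filtration",
    "PersistencePair",
    "BettiCurve",
    "build_clique_filtration",
    "boundary_of",
    "compute_persistence",
    "betti_numbers_static",
    "betti_curve",
    "essential_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Simplex:
    """A k-simplex: strictly increasing vertex tuple with a filtration value."""

    vertices: tuple[int, ...]
    value: float

    def __post_init__(self) -> None:
        if any(a >= b for a, b in zip(self.vertices, self.vertices[1:])):
            raise ValueError("simplex vertices must be strictly increasing")
        if self.value < 0:
            raise ValueError("filtration value must be non-negative")

    @property
    def dimension(self) -> int:
        return len(self.vertices) - 1


@dataclass
class Filtration:
    """Face-closed list of simplices in filtration order.

    Order is non-decreasing in value; ties broken by dimension, then
    lexicographically by vertices — deterministic and face-consistent.
    """

    simplices: list[Simplex]
    max_dimension: int
    node_count: int

    def __len__(self) -> int:
        return len(self.simplices)

    def validate(self) -> None:
        """Check ordering and face-closure; raise ValueError on violation."""
        seen: dict[tuple[int, ...], int] = {}
        prev_key = None
        for pos, s in enumerate(self.simplices):
            key = (s.value, s.dimension, s.vertices)
            if prev_key is not None and key < prev_key:
                raise ValueError("filtration order violated")
            prev_key = key
            if s.dimension > 0:
                for facet in combinations(s.vertices, len(s.vertices) - 1):
                    if facet not in seen:
                        raise ValueError(f"face-closure violated at {s.vertices}")
            seen[s.vertices] = pos


@dataclass(frozen=True)
class PersistencePair:
    """(dimension, birth, death) of one topological hole; death may be +inf."""

    dimension: int
    birth: float
    death: float

    @property
    def lifetime(self) -> float:
        return self.death - self.birth

    @property
    def essential(self) -> bool:
        return math.isinf(self.death)


@dataclass
class BettiCurve:
    """Betti numbers on a threshold grid, beta[k][i] = beta_k(thresholds[i])."""

    thresholds: np.ndarray
    beta: dict[int, np.ndarray] = field(default_factory=dict)


def _sort_key(s: Simplex) -> tuple[float, int, tuple[int, ...]]:
    return (s.value, s.dimension, s.vertices)


def build_clique_filtration(
    net: InteractionNetwork,
    max_dim: int = 3,
    weight_transform: str = "absolute",
) -> Filtration:
    """Build the sublevel clique-complex filtration of a weighted network.

    Vertices enter at 0; edge (i, j) enters at |J_ij| (``"absolute"``, the
    default) or at J_ij (``"raw"``, rejected if any weight is negative); every
    (k+1)-clique with k <= max_dim enters at the maximum of its edge values.
    """
    if max_dim < 0:
        raise ValueError("max_dim must be non-negative")
    if weight_transform not in ("absolute", "raw"):
        raise ValueError("weight_transform must be 'absolute' or 'raw'")
    W = net.weights
    if weight_transform == "raw" and np.any(W < 0):
        raise ValueError("raw weight transform requires non-negative weights")
    vals = np.abs(W) if weight_transform == "absolute" else W

    n = net.n_nodes
    simplices = [Simplex(vertices=(i,), value=0.0) for i in range(n)]
    if max_dim >= 1:
        G = nx.Graph()
        G.add_nodes_from(range(n))
        iu, ju = np.nonzero(np.triu(W, k=1))
        G.add_edges_from(zip(iu.tolist(), ju.tolist()))
        for clique in nx.enumerate_all_cliques(G):
            k = len(clique) - 1
            if k > max_dim:
                break  # cliques are enumerated in order of size
            if k == 0:
                continue
            verts = tuple(sorted(clique))
            value = max(vals[a, b] for a, b in combinations(verts, 2))
            simplices.append(Simplex(vertices=verts, value=float(value)))
    simplices.sort(key=_sort_key)
    return Filtration(simplices=simplices, max_dimension=max_dim, node_count=n)


def boundary_of(simplex: Simplex) -> list[tuple[int, ...]]:
    """Facets of a simplex, obtained by deleting each vertex in turn.

    Over Z2 the alternating orientation signs all reduce to 1, so only the
    facet list is returned; a vertex has empty boundary.
    """
    if simplex.dimension == 0:
        return []
    v = simplex.vertices
    return [v[:i] + v[i + 1:] for i in range(len(v))]


def compute_persistence(
    filt: Filtration, validate: bool = True
) -> list[PersistencePair]:
    """Standard persistence by boundary-matrix column reduction over Z2.

    Pairs are emitted for dimensions 0 .. max_dimension - 1. Unpaired classes
    get death = +inf. Zero-lifetime pairs (simultaneous insertions) are
    dropped; their count is logged. Deterministic given the filtration order.
    """
    if validate:
        filt.validate()
    index = {s.vertices: i for i, s in enumerate(filt.simplices)}
    n = len(filt.simplices)

    # Column reduction: columns[j] is the Z2 boundary chain of simplex j,
    # stored as a set of row indices; pivot maps lowest-row -> column.
    pivot: dict[int, int] = {}
    paired: set[int] = set()
    pairs: list[tuple[int, int]] = []  # (birth simplex index, death simplex index)
    reduced: dict[int, set[int]] = {}

    for j, s in enumerate(filt.simplices):
        col = {index[f] for f in boundary_of(s)}
        while col:
            low = max(col)
            other = pivot.get(low)
            if other is None:
                break
            col ^= reduced[other]
        if col:
            low = max(col)
            pivot[low] = j
            reduced[j] = col
            pairs.append((low, j))
            paired.add(low)
            paired.add(j)

    out: list[PersistencePair] = []
    dropped = 0
    for b, d in pairs:
        sb, sd = filt.simplices[b], filt.simplices[d]
        if sb.dimension >= filt.max_dimension:
            continue
        if sd.value > sb.value:
            out.append(PersistencePair(sb.dimension, sb.value, sd.value))
        else:
            dropped += 1
    for j, s in enumerate(filt.simplices):
        if j not in paired and s.dimension < filt.max_dimension:
            out.append(PersistencePair(s.dimension, s.value, math.inf))
    if dropped:
        logger.info("dropped %d zero-lifetime pairs", dropped)
    out.sort(key=lambda p: (p.dimension, p.birth, p.death))
    return out


# ---------------------------------------------------------------------------
# Rank-based oracle
# ---------------------------------------------------------------------------


def _gf2_rank(M: np.ndarray) -> int:
    """Rank of a 0/1 matrix over GF(2) by Gaussian elimination."""
    M = M.copy().astype(np.uint8)
    rows, cols = M.shape
    rank = 0
    for c in range(cols):
        pivot_row = None
        for r in range(rank, rows):
            if M[r, c]:
                pivot_row = r
                break
        if pivot_row is None:
            continue
        M[[rank, pivot_row]] = M[[pivot_row, rank]]
        mask = M[:, c].astype(bool)
        mask[rank] = False
        M[mask] ^= M[rank]
        rank += 1
        if rank == rows:
            break
    return rank


def betti_numbers_static(
    net: InteractionNetwork,
    threshold: float,
    max_dim: int = 3,
    weight_transform: str = "absolute",
    size_guard: int = 200_000,
) -> tuple[int, ...]:
    """Betti numbers (beta_0 .. beta_{max_dim-1}) of the clique complex at a
    fixed threshold, via dense Z2 boundary-matrix ranks.

    Independent of the reduction algorithm: assembles the chain groups
    directly and uses beta_k = dim C_k - rank d_k - rank d_{k+1}. Intended as
    an oracle for small complexes; refuses complexes above ``size_guard``
    simplices.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    filt = build_clique_filtration(net, max_dim=max_dim, weight_transform=weight_transform)
    by_dim: dict[int, list[tuple[int, ...]]] = {k: [] for k in range(max_dim + 1)}
    total = 0
    for s in filt.simplices:
        if s.value <= threshold:
            by_dim[s.dimension].append(s.vertices)
            total += 1
    if total > size_guard:
        raise ValueError(f"complex has {total} simplices, above oracle guard {size_guard}")

    ranks: dict[int, int] = {0: 0}
    for k in range(1, max_dim + 1):
        rows = {v: i for i, v in enumerate(by_dim[k - 1])}
        cols = by_dim[k]
        if not rows or not cols:
            ranks[k] = 0
            continue
        D = np.zeros((len(rows), len(cols)), dtype=np.uint8)
        for j, verts in enumerate(cols):
            for facet in combinations(verts, len(verts) - 1):
                D[rows[facet], j] = 1
        ranks[k] = _gf2_rank(D)

    betti = []
    for k in range(max_dim):
        betti.append(len(by_dim[k]) - ranks[k] - ranks.get(k + 1, 0))
    return tuple(betti)


def betti_curve(
    pairs: list[PersistencePair],
    thresholds: np.ndarray | None = None,
    max_dim: int = 3,
) -> BettiCurve:
    """Betti curves from persistence pairs by the half-open counting rule
    beta_k(w) = #{pairs of dimension k with birth <= w < death}.

    The default grid is the sorted distinct finite birth/death values.
    """
    if thresholds is None:
        crit = sorted({p.birth for p in pairs} | {p.death for p in pairs if not p.essential})
        thresholds = np.array(crit if crit else [0.0], dtype=float)
    else:
        thresholds = np.asarray(thresholds, dtype=float)
        if thresholds.size == 0:
            raise ValueError("threshold grid must be nonempty")
        if np.any(np.diff(thresholds) <= 0):
            raise ValueError("threshold grid must be strictly increasing")

    beta = {k: np.zeros(thresholds.size, dtype=int) for k in range(max_dim)}
    for p in pairs:
        if p.dimension >= max_dim:
            continue
        beta[p.dimension] += (thresholds >= p.birth) & (thresholds < p.death)
    return BettiCurve(thresholds=thresholds, beta=beta)


def essential_features(pairs: list[PersistencePair]) -> dict[int, list[float]]:
    """Birth values of essential (death = +inf) classes, keyed by dimension."""
    out: dict[int, list[float]] = {}
    for p in pairs:
        if p.essential:
            out.setdefault(p.dimension, []).append(p.birth)
    for births in out.values():
        births.sort()
    return out
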