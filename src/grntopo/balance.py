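"""Structural-balance energetics of the signed coupling network.

Every closed triangle (i, j, k) carries the energy E_ijk = J_ij J_jk J_ki and
is balanced when that product is positive, imbalanced (frustrated) when
negative; absent (zero-weight) edges never close a triangle, so the dichotomy
is total. The triadic Hamiltonian is H3 = -sum E_ijk. The quartic Hamiltonian
couples pairs of triangles sharing a common edge: with Delta the sign (+-1)
of a triangle's weight product, H4 = -sum_{pairs} Delta_a Delta_b = -s(G),
where s(G) is the signed square count (for an all-positive network, simply the
number of shared-edge triangle pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import InteractionNetwork

__all__ = [
    "Triad",
    "TriadCensus",
    "enumerate_triads",
    "quartic_energy",
    "energy_distribution",
]

SIGN_PATTERNS = ("+++", "++-", "+--", "---")


@dataclass(frozen=True)
class Triad:
    """A closed triangle with its three weights, energy and balance state."""

    nodes: tuple[int, int, int]
    weights: tuple[float, float, float]  # (J_ij, J_jk, J_ki) for i < j < k

    @property
    def energy(self) -> float:
        a, b, c = self.weights
        return a * b * c

    @property
    def balanced(self) -> bool:
        return self.energy > 0

    @property
    def sign_pattern(self) -> str:
        neg = sum(w < 0 for w in self.weights)
        return SIGN_PATTERNS[neg]


@dataclass
class TriadCensus:
    """All closed triangles of a network, with counts by sign pattern."""

    triads: list[Triad]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {p: 0 for p in SIGN_PATTERNS}
            for t in self.triads:
                self.counts[t.sign_pattern] += 1

    @property
    def n_balanced(self) -> int:
        return self.counts["+++"] + self.counts["+--"]

    @property
    def n_imbalanced(self) -> int:
        return self.counts["++-"] + self.counts["---"]

    @property
    def energies(self) -> np.ndarray:
        return np.array([t.energy for t in self.triads], dtype=float)

    @property
    def total_balance_energy(self) -> float:
        """Triadic Hamiltonian H = -sum over triangles of J_ij J_jk J_ki."""
        return -float(self.energies.sum()) if self.triads else 0.0


def enumerate_triads(net: InteractionNetwork) -> TriadCensus:
    """Enumerate every closed triangle of the signed network exactly once.

    Uses per-edge common-neighbour intersection, so cost scales with the
    number of triangles rather than with n^3.
    """
    W = net.weights
    n = net.n_nodes
    neighbors = [set(np.nonzero(W[i])[0].tolist()) for i in range(n)]
    triads: list[Triad] = []
    for i in range(n):
        for j in sorted(neighbors[i]):
            if j <= i:
                continue
            for k in sorted(neighbors[i] & neighbors[j]):
                if k <= j:
                    continue
                triads.append(
                    Triad(nodes=(i, j, k), weights=(W[i, j], W[j, k], W[k, i]))
                )
    return TriadCensus(triads=triads)


def quartic_energy(
    net: InteractionNetwork, census: TriadCensus | None = None, weighted: bool = False
) -> tuple[float, float]:
    """Quartic Hamiltonian over pairs of triangles sharing a common edge.

    Returns ``(H, s)`` with H = -s and s = sum over all unordered pairs of
    distinct triangles sharing exactly one edge of Delta_a * Delta_b, where
    Delta is the sign of the triangle's weight product (or the product itself
    if ``weighted``). Two distinct triangles of a simple graph can share at
    most one edge, so "sharing an edge" is unambiguous.
    """
    if census is None:
        census = enumerate_triads(net)
    per_edge: dict[tuple[int, int], list[float]] = {}
    for t in census.triads:
        delta = t.energy if weighted else float(np.sign(t.energy))
        i, j, k = t.nodes
        for edge in ((i, j), (j, k), (i, k)):
            per_edge.setdefault(edge, []).append(delta)
    s = 0.0
    for deltas in per_edge.values():
        arr = np.array(deltas)
        # sum over unordered pairs: ((sum)^2 - sum of squares) / 2
        s += (arr.sum() ** 2 - (arr**2).sum()) / 2
    if not weighted:
        s = round(s)
    return -s, s


def energy_distribution(
    census: TriadCensus,
    bins: int | np.ndarray = 20,
    by_pattern: bool = False,
) -> dict:
    """Histogram of triangle energies E_ijk, optionally split by sign pattern.

    Returns a dict with ``edges``, ``counts`` and, if requested,
    ``counts_by_pattern``.
    """
    energies = census.energies
    if energies.size == 0:
        raise ValueError("cannot histogram an empty census")
    counts, edges = np.histogram(energies, bins=bins)
    out = {"edges": edges, "counts": counts}
    if by_pattern:
        out["counts_by_pattern"] = {
            p: np.histogram(
                np.array([t.energy for t in census.triads if t.sign_pattern == p]),
                bins=edges,
            )[0]
            for p in SIGN_PATTERNS
        }
    return out
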