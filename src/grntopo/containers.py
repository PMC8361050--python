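"""Core data containers shared across the pipeline.

An :class:`ExpressionMatrix` holds real-valued expression levels (genes x
samples); a :class:`CovarianceModel` holds the first and second moments that
parameterize the maximum-entropy Gaussian model; an
:class:`InteractionNetwork` holds the signed symmetric coupling matrix J
inferred from the precision matrix (J_ij = -Theta_ij off the diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "CovarianceModel", "InteractionNetwork"]


@dataclass
class ExpressionMatrix:
    """Genes x samples table of real expression values.

    Rows are genes, columns are samples. Values may be RPKM or arbitrary
    continuous units; no missing values are allowed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample identifiers must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        """Write as tab-separated text: first column gene ID, header of sample IDs."""
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )


@dataclass
class CovarianceModel:
    """First and second moments of the maximum-entropy Gaussian model.

    ``mean`` is the per-gene sample mean <S>; ``covariance`` is the
    maximum-likelihood (divisor n) gene-gene covariance matrix C. The Gaussian
    normalizer (2 pi)^{L/2} det(C)^{1/2} is closed-form and not stored.
    """

    gene_ids: list[str]
    mean: np.ndarray
    covariance: np.ndarray
    n_samples_used: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        L = len(self.gene_ids)
        if self.mean.shape != (L,) or self.covariance.shape != (L, L):
            raise ValueError("mean/covariance dimensions do not match gene_ids")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.any(np.diag(self.covariance) <= 0):
            raise ValueError(
                "covariance has non-positive diagonal entries; "
                "zero-variance genes must be removed before model fitting"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class InteractionNetwork:
    """Symmetric signed weighted coupling matrix J over genes, zero diagonal."""

    gene_ids: list[str]
    weights: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match gene_ids")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("interaction matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("interaction matrix must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def sparsity(self) -> float:
        """Fraction of zero off-diagonal entries."""
        n = self.n_nodes
        if n < 2:
            return 1.0
        off = n * (n - 1)
        nz = np.count_nonzero(self.weights) - np.count_nonzero(np.diag(self.weights))
        return 1.0 - nz / off

    def edges(self) -> list[tuple[int, int, float]]:
        """Nonzero unordered pairs (i, j, weight) with i < j."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        w = self.weights[iu, ju]
        keep = w != 0
        return list(zip(iu[keep].tolist(), ju[keep].tolist(), w[keep].tolist()))

    def edge_weights(self) -> np.ndarray:
        """Signed weights of present edges (one value per unordered pair)."""
        return np.array([w for _, _, w in self.edges()], dtype=float)

    def to_edgelist_tsv(self, path: str | Path) -> None:
        """Write signed edge list: gene_i, gene_j, weight; i before j in ID order."""
        with open(path, "w") as fh:
            fh.write("gene_i\tgene_j\tweight\n")
            for i, j, w in self.edges():
                fh.write(f"{self.gene_ids[i]}\t{self.gene_ids[j]}\t{w:.17g}\n")

    @classmethod
    def from_edgelist_tsv(cls, path: str | Path) -> "InteractionNetwork":
        df = pd.read_csv(path, sep="\t")
        names: list[str] = []
        seen: set[str] = set()
        for col in ("gene_i", "gene_j"):
            for g in df[col].astype(str):
                if g not in seen:
                    seen.add(g)
                    names.append(g)
        names = sorted(names)
        idx = {g: k for k, g in enumerate(names)}
        W = np.zeros((len(names), len(names)))
        for a, b, w in zip(df["gene_i"].astype(str), df["gene_j"].astype(str), df["weight"]):
            W[idx[a], idx[b]] = w
            W[idx[b], idx[a]] = w
        return cls(gene_ids=names, weights=W)
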