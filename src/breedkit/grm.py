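"""VanRaden genomic relationship matrix, PCA of lines, and clustering order.

G = ZZ' / (2 * sum_i p_i (1 - p_i)) with Z = M - P, where M holds the
-1/0/+1 marker codes and the i-th column of P is 2(p_i - 0.5).  Allele
frequencies are always recomputed from the matrix G is built from, so the
columns of Z have mean zero and G is invariant to flipping which allele is
counted at any marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .markers import MarkerMatrix, allele_frequencies

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """Symmetric line x line genomic relationship matrix."""

    values: np.ndarray
    line_ids: list
    scale_denominator: float  # 2 * sum p_i (1 - p_i)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        if self.scale_denominator <= 0:
            raise ValueError("scale denominator must be positive")

    @property
    def n(self) -> int:
        return len(self.line_ids)

    def subset(self, line_ids) -> "GRM":
        """Marginal relationship matrix for a subset of lines."""
        idx = [self.line_ids.index(l) for l in line_ids]
        return GRM(self.values[np.ix_(idx, idx)], list(line_ids), self.scale_denominator)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "GRM":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        vals = df.to_numpy(dtype=float)
        vals = 0.5 * (vals + vals.T)  # CSV round-trip symmetrization
        denom = 1.0  # denominator is not stored in the CSV; kept for API shape
        return cls(vals, list(df.index), denom)

    def chol_inverse(self, jitter_base: float = 1e-6, max_tries: int = 6) -> np.ndarray:
        """Inverse via Cholesky with PSD repair: on failure add eps*I with
        eps = jitter_base * mean(diag), escalating tenfold, and log it."""
        from scipy.linalg import cho_factor, cho_solve

        eps = 0.0
        step = jitter_base * float(np.mean(np.diag(self.values)))
        for _ in range(max_tries):
            try:
                c = cho_factor(self.values + eps * np.eye(self.n), lower=True)
                if eps > 0:
                    logger.warning("GRM not positive definite; added %.3g * I", eps)
                return cho_solve(c, np.eye(self.n))
            except np.linalg.LinAlgError:
                eps = step if eps == 0.0 else eps * 10.0
        raise np.linalg.LinAlgError("GRM could not be repaired to positive definite")


@dataclass
class PCAResult:
    """Principal components of the relationship matrix."""

    eigenvalues: np.ndarray  # descending
    proportion_variance: np.ndarray  # per retained component
    scores: pd.DataFrame  # lines x components
    centered: bool

    def __post_init__(self) -> None:
        if np.any(np.diff(self.proportion_variance) > 1e-12):
            raise ValueError("proportions must be non-increasing")


def build_grm(m: MarkerMatrix) -> GRM:
    """Build the genomic relationship matrix from an imputed marker matrix."""
    if m.missing_mask.any():
        raise ValueError("build_grm needs an imputed matrix (no missing calls)")
    if m.n_lines < 2:
        raise ValueError("need at least two lines")
    p = allele_frequencies(m)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero GRM denominator")
    z = m.values - 2.0 * (p - 0.5)[np.newaxis, :]
    g = (z @ z.T) / denom
    g = 0.5 * (g + g.T)
    return GRM(g, list(m.line_ids), denom)


def pca(g: GRM, k: int | None = None, center: bool = True) -> PCAResult:
    """PCA of the relationship matrix, treating G as a lines x lines data
    matrix whose columns are centered by default (prcomp-style).

    Proportions of variance are eigenvalue / total variance of the (centered)
    matrix; scores are the projections of the lines on the components.
    """
    n = g.n
    if k is None:
        k = n
    if k > n:
        raise ValueError(f"k={k} exceeds number of lines {n}")
    x = g.values - g.values.mean(axis=0, keepdims=True) if center else g.values.copy()
    # SVD of the (centered) data matrix; eigenvalues of the covariance
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    scores = u * s
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        eigenvalues=eig[:k],
        proportion_variance=eig[:k] / total,
        scores=pd.DataFrame(scores[:, :k], index=g.line_ids, columns=cols),
        centered=center,
    )


def cluster_order(g: GRM) -> tuple[list, np.ndarray]:
    """Complete-linkage agglomerative clustering on the relationship-derived
    distance d(i,j) = G_ii + G_jj - 2 G_ij.

    Returns the leaf order (a permutation of line_ids) and the scipy merge
    table (heights included), which together define a heat-map ordering.
    """
    d = np.add.outer(np.diag(g.values), np.diag(g.values)) - 2.0 * g.values
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)  # numerical guard: distances cannot be negative
    merges = linkage(squareform(d, checks=False), method="complete")
    order = [g.line_ids[i] for i in leaves_list(merges)]
    return order, merges
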