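"""Genomic relationship matrix (VanRaden method 1).

With dosage matrix M (n x L) and observed allele frequencies
p_j = mean(M[:, j]) / 2, the centered matrix W has columns
W[:, j] = M[:, j] - 2 p_j and

    K = W W' / (2 * sum_j p_j (1 - p_j)).

Monomorphic markers carry no relationship information and are excluded
from both W and the denominator. The eigendecomposition of K is computed
once and cached on the object; both the REML and the Gibbs GBLUP fits work
in this eigenbasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix


class DegenerateKinshipError(ValueError):
    """All markers monomorphic: no genomic relationship can be formed."""


@dataclass
class KinshipMatrix:
    """n x n genomic relationship matrix with cached eigendecomposition."""

    matrix: np.ndarray
    sample_ids: np.ndarray
    source: str = "vanraden1"
    _eigenvalues: np.ndarray | None = field(default=None, repr=False)
    _eigenvectors: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=np.float64)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(K, K.T, atol=1e-8 * max(1.0, np.abs(K).max())):
            raise ValueError("kinship matrix is not symmetric")
        self.matrix = (K + K.T) / 2.0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def _ensure_eigen(self) -> None:
        if self._eigenvalues is None:
            vals, vecs = np.linalg.eigh(self.matrix)
            floor = -1e-8 * max(vals.max(), 1.0)
            if vals.min() < floor:
                raise ValueError("kinship matrix has a substantially negative eigenvalue")
            self._eigenvalues = np.maximum(vals, 0.0)
            self._eigenvectors = vecs

    @property
    def eigenvalues(self) -> np.ndarray:
        self._ensure_eigen()
        return self._eigenvalues

    @property
    def eigenvectors(self) -> np.ndarray:
        self._ensure_eigen()
        return self._eigenvectors

    def submatrix(self, idx: np.ndarray) -> "KinshipMatrix":
        """Kinship restricted to samples ``idx`` (fresh eigencache)."""
        idx = np.asarray(idx, dtype=np.intp)
        return KinshipMatrix(
            matrix=self.matrix[np.ix_(idx, idx)],
            sample_ids=self.sample_ids[idx],
            source=self.source,
        )

    def cross(self, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
        """Rectangular block K[idx_a, idx_b]."""
        return self.matrix[np.ix_(np.asarray(idx_a, dtype=np.intp),
                                  np.asarray(idx_b, dtype=np.intp))]


def centered_dosages(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (W, 2p, denominator) for the polymorphic markers of ``g``.

    W's columns sum to zero exactly up to floating-point rounding; the
    denominator is 2 * sum_j p_j (1 - p_j) over polymorphic markers only.
    """
    if g.missing_mask.any():
        raise ValueError("missing dosages present; run drop_incomplete_markers first")
    M = g.dosages.astype(np.float64)
    p = M.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise DegenerateKinshipError("all markers are monomorphic")
    M = M[:, poly]
    p = p[poly]
    W = M - 2.0 * p
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    return W, 2.0 * p, denom


def compute_grm(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden method-1 GRM from observed allele frequencies."""
    W, _, denom = centered_dosages(g)
    K = (W @ W.T) / denom
    return KinshipMatrix(matrix=K, sample_ids=g.sample_ids.copy())
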