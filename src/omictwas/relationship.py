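"""Expression-level-based relationship matrix (ORM).

The ORM plays the role a genomic relationship matrix plays in GREML: its
entry for individuals j and k is the average over features of the product
of their standardized expression values,

    A_jk = (1/m) * sum_i (x_ij - mu_i)(x_ik - mu_i) / sigma_i^2,

i.e. A = Z'Z/m with Z the (features x individuals) standardized expression
matrix.  Under population-variance standardization every diagonal averages
to exactly 1 (trace(A) = n), which is what lets the REML variance ratio be
read as the proportion of phenotypic variance tied to global expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix

__all__ = ["RelationshipMatrix", "build_orm"]


@dataclass
class RelationshipMatrix:
    """n x n symmetric PSD relationship matrix with a lazily cached
    spectral decomposition (one O(n^3) eigendecomposition, reused by REML
    and every association scan)."""

    A: np.ndarray
    m_features: int
    individual_ids: list[str]
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids must match A's dimension")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("A must be symmetric")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending, clipped at 0) and eigenvectors of A."""
        if self._eig is None:
            lam, U = np.linalg.eigh(self.A)
            if lam.min() < -1e-8 * max(1.0, abs(lam.max())):
                raise ValueError("A is not positive semi-definite")
            self._eig = (np.clip(lam, 0.0, None), U)
        return self._eig


def build_orm(std_expr: ExpressionMatrix) -> RelationshipMatrix:
    """Build A = Z'Z/m from a standardized expression matrix."""
    if std_expr.scale_tag != "standardized":
        raise ValueError("build_orm expects a standardized ExpressionMatrix")
    if std_expr.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    z = std_expr.values
    m = z.shape[0]
    if m < 1:
        raise ValueError("need at least one feature")
    A = z.T @ z / m
    A = (A + A.T) / 2.0  # exact symmetry against round-off
    return RelationshipMatrix(
        A=A, m_features=m, individual_ids=list(std_expr.individual_ids)
    )
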