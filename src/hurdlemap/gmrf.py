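"""Intrinsic Gaussian Markov random field machinery.

Builds the sparse precision structures used by the latent model: the
intrinsic CAR precision ``D - W`` for spatial effects and the
first-order random-walk penalty for temporal effects.  Both are rank
deficient (one null dimension per connected component, one for the
random walk), so densities are evaluated on the sum-to-zero constrained
subspace with a rank-adjusted log-determinant.

Following the modern (BYM2-style) convention, intrinsic structures are
scaled so that the geometric mean of the constrained marginal variances
equals one; the scaling factor is computed from a dense eigendecomposition,
which is exact and affordable at the problem sizes this package targets
(up to a few thousand areas).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp

from .graph import AreaGraph

__all__ = [
    "PrecisionStructure",
    "icar_precision",
    "rw1_precision",
    "structured_logpdf",
    "sample_structured",
]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class PrecisionStructure:
    """An (unscaled) intrinsic precision matrix with its spectral metadata.

    ``scaling`` is the BYM2/RW generalised-variance factor: the field with
    precision ``scaling * Q`` has constrained marginal variances whose
    geometric mean is one (computed over non-isolated nodes).
    """

    Q: sp.csr_matrix
    rank_deficiency: int
    scaling: float
    eigvals: np.ndarray  # ascending eigenvalues of Q (dense spectrum)
    eigvecs: np.ndarray  # corresponding orthonormal eigenvectors (columns)

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @cached_property
    def positive_eigvals(self) -> np.ndarray:
        tol = max(self.eigvals.max(), 1.0) * _EIG_TOL
        return self.eigvals[self.eigvals > tol]

    @cached_property
    def _pos_mask(self) -> np.ndarray:
        tol = max(self.eigvals.max(), 1.0) * _EIG_TOL
        return self.eigvals > tol

    @cached_property
    def marginal_variances(self) -> np.ndarray:
        """Diagonal of the constrained generalised inverse of ``Q``."""
        v = self.eigvecs[:, self._pos_mask]
        lam = self.eigvals[self._pos_mask]
        return (v**2 / lam).sum(axis=1)

    @property
    def log_det_scaled(self) -> float:
        """Sum of log positive eigenvalues of ``scaling * Q``."""
        return float(np.sum(np.log(self.scaling * self.positive_eigvals)))


def _build_structure(q_sparse: sp.csr_matrix, rank_deficiency: int) -> PrecisionStructure:
    qd = q_sparse.toarray()
    eigvals, eigvecs = np.linalg.eigh(qd)
    tol = max(eigvals.max(), 1.0) * _EIG_TOL
    pos = eigvals > tol
    if pos.sum() == 0:
        # edgeless graph: no structured variation, scaling is a no-op
        return PrecisionStructure(q_sparse, rank_deficiency, 1.0, eigvals, eigvecs)
    v = eigvecs[:, pos]
    marg = (v**2 / eigvals[pos]).sum(axis=1)
    active = marg > tol  # isolated nodes have zero constrained variance
    scaling = float(np.exp(np.mean(np.log(marg[active]))))
    return PrecisionStructure(q_sparse, rank_deficiency, scaling, eigvals, eigvecs)


def icar_precision(graph: AreaGraph) -> PrecisionStructure:
    """Intrinsic CAR precision ``Q = D - W`` on the area graph.

    Rank deficiency equals the number of connected components (isolated
    nodes each count as a component and contribute no structured
    variation).  Every row of ``Q`` sums to zero.
    """
    w = graph.adjacency
    d = sp.diags(graph.degrees.astype(float))
    q = (d - w).tocsr()
    return _build_structure(q, graph.n_components)


def rw1_precision(n_years: int) -> PrecisionStructure:
    """First-difference (random-walk of order 1) penalty matrix.

    ``x' Q x = sum_t (x[t+1] - x[t])^2``; tridiagonal, rank deficiency 1.
    """
    if n_years < 2:
        raise ValueError(f"rw1_precision requires n_years >= 2, got {n_years}")
    main = np.full(n_years, 2.0)
    main[0] = main[-1] = 1.0
    off = np.full(n_years - 1, -1.0)
    q = sp.diags([off, main, off], offsets=[-1, 0, 1]).tocsr()
    return _build_structure(q, 1)


def structured_logpdf(x: np.ndarray, structure: PrecisionStructure) -> float:
    """Log density of the scaled intrinsic field on its constrained subspace.

    The field has precision ``scaling * Q`` restricted to the orthogonal
    complement of the null space (sum-to-zero within each component for
    the ICAR, overall for the RW1).  The caller is responsible for ``x``
    satisfying the constraint.
    """
    m = structure.n - structure.rank_deficiency
    if m <= 0:
        return 0.0
    quad = float(x @ (structure.Q @ x))
    return 0.5 * structure.log_det_scaled - 0.5 * m * np.log(2 * np.pi) \
        - 0.5 * structure.scaling * quad


def sample_structured(structure: PrecisionStructure, rng: np.random.Generator) -> np.ndarray:
    """Draw the scaled intrinsic field (exactly on the constrained subspace)."""
    mask = structure._pos_mask
    lam = structure.eigvals[mask]
    v = structure.eigvecs[:, mask]
    z = rng.standard_normal(lam.size)
    return v @ (z / np.sqrt(structure.scaling * lam))
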