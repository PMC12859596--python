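"""Penalised-complexity (PC) hyperpriors.

Precisions carry the standard PC prior derived from an exponential on
the standard-deviation scale: stating ``P(1/sqrt(tau) > u) = alpha``
gives sigma ~ Exp(lambda) with ``lambda = -log(alpha) / u`` and

    pi(tau) = (lambda / 2) * tau^(-3/2) * exp(-lambda / sqrt(tau)).

The BYM2 mixing parameter phi carries the PC prior built from the
Kullback-Leibler distance between the mixed field and its unstructured
base model; this depends on the spectrum of the scaled structured
covariance and is evaluated on a grid.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "pc_precision_lambda",
    "pc_precision_logpdf",
    "pc_precision_sample",
    "PCMixingPrior",
]


def pc_precision_lambda(u: float, alpha: float) -> float:
    if u <= 0 or not (0 < alpha < 1):
        raise ValueError("PC prior requires u > 0 and alpha in (0, 1)")
    return -np.log(alpha) / u


def pc_precision_logpdf(tau: float | np.ndarray, u: float, alpha: float) -> np.ndarray:
    """Log density of the PC precision prior with P(sigma > u) = alpha."""
    lam = pc_precision_lambda(u, alpha)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("precision must be positive")
    return np.log(lam / 2) - 1.5 * np.log(tau) - lam / np.sqrt(tau)


def pc_precision_sample(
    rng: np.random.Generator, u: float, alpha: float, size: int | None = None
):
    """Draw precisions: sigma ~ Exp(lambda), tau = sigma^-2."""
    lam = pc_precision_lambda(u, alpha)
    sigma = rng.exponential(1.0 / lam, size=size)
    return sigma**-2.0


class PCMixingPrior:
    """PC prior for the BYM2 mixing parameter phi in [0, 1].

    Parameters
    ----------
    marginal_eigvals:
        Eigenvalues of the scaled structured covariance on the
        constrained subspace (``1 / (scaling * lambda_i)`` for the
        positive ICAR eigenvalues).
    u, alpha:
        Tail statement ``P(phi < u) = alpha``.  When the statement is
        unattainable for the given spectrum (the distance scale alone
        already puts more mass below ``u``), the prior falls back to the
        base-rate limit, i.e. uniform on the KL distance scale.
    """

    def __init__(
        self,
        marginal_eigvals: np.ndarray,
        u: float = 0.5,
        alpha: float = 0.5,
        grid_size: int = 2001,
    ):
        e = np.asarray(marginal_eigvals, dtype=float)
        if e.size == 0 or np.any(e <= 0):
            raise ValueError("need positive covariance eigenvalues")
        if not (0 < u < 1) or not (0 < alpha < 1):
            raise ValueError("require u, alpha in (0, 1)")
        self.u, self.alpha = u, alpha
        hi = 1.0 - 1e-7
        self.grid = np.linspace(0.0, hi, grid_size)
        em1 = e - 1.0
        kld = 0.5 * np.sum(
            self.grid[:, None] * em1[None, :]
            - np.log1p(self.grid[:, None] * em1[None, :]),
            axis=1,
        )
        kld = np.maximum(kld, 0.0)
        self.dist = np.sqrt(2.0 * kld)
        d_u = np.interp(u, self.grid, self.dist)
        d_max = self.dist[-1]

        def cdf_at_u(lam: float) -> float:
            return float(-np.expm1(-lam * d_u) / -np.expm1(-lam * d_max))

        # As lambda -> 0 the CDF tends to d_u / d_max; larger lambda moves
        # mass toward phi = 0.  The statement is attainable iff
        # alpha >= d_u / d_max.
        if alpha >= d_u / d_max + 1e-12:
            self.lam = brentq(lambda l: cdf_at_u(l) - alpha, 1e-8, 1e6)
            self.attainable = True
        else:
            self.lam = 1e-8
            self.attainable = False

        # unnormalised log density on the grid, then normalise numerically
        ddist = np.gradient(self.dist, self.grid)
        ddist = np.maximum(ddist, 1e-300)
        log_pdf = -self.lam * self.dist + np.log(ddist)
        log_pdf -= log_pdf.max()
        pdf = np.exp(log_pdf)
        norm = np.trapezoid(pdf, self.grid)
        self._pdf_grid = pdf / norm
        self._log_pdf_grid = np.log(self._pdf_grid)
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (self._pdf_grid[1:] + self._pdf_grid[:-1]) * np.diff(self.grid))])
        self._cdf_grid = cdf / cdf[-1]

    def logpdf(self, phi: float | np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        if np.any((phi < 0) | (phi > 1)):
            raise ValueError("phi must lie in [0, 1]")
        return np.interp(phi, self.grid, self._log_pdf_grid)

    def cdf(self, phi: float) -> float:
        return float(np.interp(phi, self.grid, self._cdf_grid))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        u = rng.random(size)
        return np.interp(u, self._cdf_grid, self.grid)
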