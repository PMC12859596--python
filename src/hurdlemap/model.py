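"""The shared-component hurdle Poisson model.

Counts ``y(i, t)`` of a rare event in area ``i`` and year ``t`` are
modelled in two parts: a Bernoulli gate for whether any event occurs,
and a zero-truncated Poisson for the size of a non-zero count,

    P(y = 0)          = 1 - pi
    P(y = k), k >= 1  = pi * mu^k e^{-mu} / (k! (1 - e^{-mu}))

with component-specific linear predictors

    log mu   = log E + alpha_p + x' beta_p + b_i + gamma_t + phi_t + psi_it
    logit pi =         alpha_b + x' beta_b
               + delta_s * b_i + delta_t * (gamma_t + phi_t) + delta_st * psi_it

where ``E`` is the indirectly standardised expected count (the offset,
count component only), ``b`` is a BYM2 spatial effect, ``gamma`` a
first-order random walk in time, ``phi_t`` an exchangeable temporal
effect, and ``psi`` an exchangeable space-time interaction.  The gate
borrows the count component's random effects through scalar sharing
coefficients ``delta``.

Latent fields are held in a non-centred parameterisation: standardised
fields (``u, v, w, z_t, z_st``) with fixed unit-scale priors, scaled by
``1/sqrt(tau)`` inside the predictors.  Precisions carry PC priors, the
BYM2 mixing parameter its spectrum-dependent PC prior, and intercepts,
covariate coefficients and log sharing scales Gaussian priors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .data import CovariateMatrix, ExpectedCounts
from .gmrf import (
    PrecisionStructure,
    icar_precision,
    rw1_precision,
    sample_structured,
    structured_logpdf,
)
from .graph import AreaGraph
from .priors import PCMixingPrior, pc_precision_logpdf, pc_precision_sample

__all__ = [
    "ModelSpec",
    "Params",
    "HurdleModel",
    "linear_predictors",
    "hurdle_loglik",
    "log_posterior",
    "icar_precision",
    "rw1_precision",
]

_CONSTRAINT_TOL = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """Prior and structure choices for the hurdle model.

    ``pc_u``/``pc_alpha`` give the PC-prior tail statement
    ``P(1/sqrt(tau) > pc_u) = pc_alpha`` shared by all precisions;
    ``pc_u_phi``/``pc_alpha_phi`` state ``P(phi < u) = alpha`` for the
    BYM2 mixing parameter.  ``share_scales_free`` toggles whether the
    gate's sharing coefficients are estimated or pinned at one.
    """

    include_spatial: bool = True
    include_temporal: bool = True
    include_interaction: bool = True
    share_scales_free: bool = True
    pc_u: float = 1.0
    pc_alpha: float = 0.01
    pc_u_phi: float = 0.5
    pc_alpha_phi: float = 0.5
    intercept_sd: float = 10.0
    beta_sd: float = 10.0
    share_log_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pc_u", "pc_u_phi", "intercept_sd", "beta_sd", "share_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pc_alpha", "pc_alpha_phi"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


@dataclass
class Params:
    """Full latent state of the model.

    Standardised fields: ``u`` (structured spatial, sum-to-zero per graph
    component), ``v`` (unstructured spatial), ``w`` (structured temporal,
    sum-to-zero), ``z_t`` (exchangeable temporal), ``z_st`` (space-time).
    The composite effects on the predictor scale are exposed as the
    properties ``b``, ``gamma``, ``phi_t`` and ``psi``.
    """

    alpha_p: float
    alpha_b: float
    beta_p: np.ndarray
    beta_b: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau_b: float
    phi: float
    w: np.ndarray
    tau_gamma: float
    z_t: np.ndarray
    tau_t: float
    z_st: np.ndarray
    tau_st: float
    delta_s: float = 1.0
    delta_t: float = 1.0
    delta_st: float = 1.0

    def __post_init__(self) -> None:
        for name in ("beta_p", "beta_b", "u", "v", "w", "z_t"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.z_st = np.asarray(self.z_st, dtype=float)
        if self.z_st.ndim != 2:
            raise ValueError("z_st must be (n_areas, n_years)")

    # -- composite effects --------------------------------------------
    @property
    def b(self) -> np.ndarray:
        """BYM2 spatial effect (sqrt(phi) u + sqrt(1-phi) v) / sqrt(tau_b)."""
        return (np.sqrt(self.phi) * self.u + np.sqrt(1.0 - self.phi) * self.v) \
            / np.sqrt(self.tau_b)

    @property
    def gamma(self) -> np.ndarray:
        return self.w / np.sqrt(self.tau_gamma)

    @property
    def phi_t(self) -> np.ndarray:
        return self.z_t / np.sqrt(self.tau_t)

    @property
    def psi(self) -> np.ndarray:
        return self.z_st / np.sqrt(self.tau_st)

    def copy(self) -> "Params":
        return Params(
            self.alpha_p, self.alpha_b,
            self.beta_p.copy(), self.beta_b.copy(),
            self.u.copy(), self.v.copy(), self.tau_b, self.phi,
            self.w.copy(), self.tau_gamma,
            self.z_t.copy(), self.tau_t,
            self.z_st.copy(), self.tau_st,
            self.delta_s, self.delta_t, self.delta_st,
        )

    def validate(self, component_labels: np.ndarray | None = None) -> None:
        for name in ("tau_b", "tau_gamma", "tau_t", "tau_st"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")
        if abs(self.w.mean()) > _CONSTRAINT_TOL if self.w.size else False:
            raise ValueError("temporal structured effect must sum to zero")
        if component_labels is not None and self.u.size:
            for c in np.unique(component_labels):
                mask = component_labels == c
                if mask.sum() > 1 and abs(self.u[mask].mean()) > _CONSTRAINT_TOL:
                    raise ValueError(
                        f"structured spatial effect must sum to zero within component {c}"
                    )


# ---------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------

def _cell_loglik_eta(y: np.ndarray, eta_b: np.ndarray, eta_p: np.ndarray) -> np.ndarray:
    """Per-cell hurdle log-likelihood from the linear predictors.

    Numerically stable: log(1-pi) = -softplus(eta_b), log pi = eta_b -
    softplus(eta_b), and the ZTP normalisation log(1 - e^{-mu}) via
    expm1.  Overflow in exp(eta_p) propagates to -inf, which a sampler
    treats as rejection.
    """
    softplus = np.logaddexp(0.0, eta_b)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        mu = np.exp(eta_p)
        # log(1 - e^-mu); for tiny mu this is log(mu) = eta_p, which stays
        # finite even when mu itself underflows to zero
        log_norm = np.where(mu < 1e-10, eta_p, np.log(-np.expm1(-np.minimum(mu, 7e2))))
        pos = eta_b - softplus + y * eta_p - mu - gammaln(y + 1.0) - log_norm
    out = np.where(y == 0, -softplus, pos)
    return np.where(np.isnan(out), -np.inf, out)


def hurdle_loglik(y: np.ndarray, pi: np.ndarray, mu: np.ndarray) -> float:
    """Total hurdle log-likelihood over all cells.

    ``log(1 - pi)`` for zero cells; ``log pi + log ZTP(y; mu)`` for
    positive counts.  ``pi`` must lie in (0, 1) and ``mu`` must be
    positive wherever ``y >= 1``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must contain non-negative integers")
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("pi must lie strictly in (0, 1)")
    if np.any(mu[np.broadcast_to(y, np.broadcast_shapes(y.shape, mu.shape)) >= 1] <= 0):
        raise ValueError("mu must be positive wherever y >= 1")
    zero = y == 0
    ll = np.where(
        zero,
        np.log1p(-pi),
        np.log(pi) + y * np.log(np.where(zero, 1.0, mu)) - mu
        - gammaln(y + 1.0) - np.log(-np.expm1(-mu)),
    )
    return float(ll.sum())


def linear_predictors(
    params: Params,
    covariates: CovariateMatrix | np.ndarray,
    E: ExpectedCounts | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (eta_b, eta_p), the gate and count linear predictors.

    ``pi = expit(eta_b)`` and ``mu = exp(eta_p)``; the offset ``log E``
    enters the count component only.
    """
    x = covariates.values if isinstance(covariates, CovariateMatrix) else np.asarray(covariates, float)
    e = E.values if isinstance(E, ExpectedCounts) else np.asarray(E, dtype=float)
    if np.any(e <= 0):
        raise ValueError("expected counts must be strictly positive")
    b = params.b
    gam = params.gamma + params.phi_t
    psi = params.psi
    xb_p = x @ params.beta_p
    xb_b = x @ params.beta_b
    eta_p = np.log(e) + params.alpha_p + xb_p[:, None] + b[:, None] + gam[None, :] + psi
    eta_b = (
        params.alpha_b + xb_b[:, None] + params.delta_s * b[:, None]
        + params.delta_t * gam[None, :] + params.delta_st * psi
    )
    return eta_b, eta_p


# ---------------------------------------------------------------------
# the assembled model
# ---------------------------------------------------------------------

class HurdleModel:
    """Data, precision structures and priors bound together.

    Precomputes the scaled ICAR and RW1 structures and the PC prior for
    the mixing parameter, and evaluates the joint log posterior.
    """

    def __init__(
        self,
        y: np.ndarray,
        E: np.ndarray | ExpectedCounts,
        covariates: np.ndarray | CovariateMatrix,
        graph: AreaGraph,
        spec: ModelSpec | None = None,
    ) -> None:
        self.spec = spec or ModelSpec()
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be (n_areas, n_years)")
        if np.any(self.y < 0) or not np.allclose(self.y, np.round(self.y)):
            raise ValueError("y must contain non-negative integers")
        self.E = E.values if isinstance(E, ExpectedCounts) else np.asarray(E, dtype=float)
        if self.E.shape != self.y.shape:
            raise ValueError("E and y shapes differ")
        if np.any(self.E <= 0):
            raise ValueError("expected counts must be strictly positive everywhere")
        self.x = covariates.values if isinstance(covariates, CovariateMatrix) \
            else np.asarray(covariates, dtype=float)
        self.n_areas, self.n_years = self.y.shape
        if self.x.shape[0] != self.n_areas:
            raise ValueError("covariate rows must match n_areas")
        if graph.n_areas != self.n_areas:
            raise ValueError("graph size must match n_areas")
        self.k = self.x.shape[1]
        self.graph = graph
        self.log_e = np.log(self.E)

        self.spatial: PrecisionStructure | None = None
        self.phi_prior: PCMixingPrior | None = None
        if self.spec.include_spatial:
            self.spatial = icar_precision(graph)
            if self.spatial.positive_eigvals.size:
                cov_eigs = 1.0 / (self.spatial.scaling * self.spatial.positive_eigvals)
                self.phi_prior = PCMixingPrior(
                    cov_eigs, self.spec.pc_u_phi, self.spec.pc_alpha_phi
                )
        self.temporal: PrecisionStructure | None = None
        if self.spec.include_temporal:
            if self.n_years < 2:
                raise ValueError(
                    "temporal effects require n_years >= 2; "
                    "set include_temporal=False for single-year data"
                )
            self.temporal = rw1_precision(self.n_years)

    # -- parameter construction ---------------------------------------
    def zero_params(self) -> Params:
        n, t, k = self.n_areas, self.n_years, self.k
        return Params(
            0.0, 0.0, np.zeros(k), np.zeros(k),
            np.zeros(n), np.zeros(n), 1.0, 0.5,
            np.zeros(t), 1.0, np.zeros(t), 1.0,
            np.zeros((n, t)), 1.0,
        )

    def init_params(self, rng: np.random.Generator, jitter: float = 0.1) -> Params:
        """Dispersed but sane starting state for one chain."""
        p = self.zero_params()
        sp_ = self.spec
        p.alpha_p = jitter * rng.standard_normal()
        p.alpha_b = jitter * rng.standard_normal()
        p.beta_p = jitter * rng.standard_normal(self.k)
        p.beta_b = jitter * rng.standard_normal(self.k)
        lam = -np.log(sp_.pc_alpha) / sp_.pc_u
        tau_med = (np.log(2.0) / lam) ** -2.0  # PC-prior median precision
        if sp_.include_spatial:
            p.u = jitter * rng.standard_normal(self.n_areas)
            self._center_u(p.u)
            p.v = jitter * rng.standard_normal(self.n_areas)
            p.tau_b = tau_med * np.exp(jitter * rng.standard_normal())
            p.phi = float(np.clip(0.5 + jitter * rng.standard_normal(), 0.05, 0.95))
        if sp_.include_temporal:
            p.w = jitter * rng.standard_normal(self.n_years)
            p.w -= p.w.mean()
            p.z_t = jitter * rng.standard_normal(self.n_years)
            p.tau_gamma = tau_med * np.exp(jitter * rng.standard_normal())
            p.tau_t = tau_med * np.exp(jitter * rng.standard_normal())
        if sp_.include_interaction:
            p.z_st = jitter * rng.standard_normal((self.n_areas, self.n_years))
            p.tau_st = tau_med * np.exp(jitter * rng.standard_normal())
        if sp_.share_scales_free:
            p.delta_s = float(np.exp(jitter * rng.standard_normal()))
            p.delta_t = float(np.exp(jitter * rng.standard_normal()))
            p.delta_st = float(np.exp(jitter * rng.standard_normal()))
        return p

    def sample_params_from_prior(self, rng: np.random.Generator) -> Params:
        """Joint prior draw (used for prior-predictive and calibration checks)."""
        p = self.zero_params()
        sp_ = self.spec
        p.alpha_p = sp_.intercept_sd * rng.standard_normal()
        p.alpha_b = sp_.intercept_sd * rng.standard_normal()
        p.beta_p = sp_.beta_sd * rng.standard_normal(self.k)
        p.beta_b = sp_.beta_sd * rng.standard_normal(self.k)
        if sp_.include_spatial and self.spatial is not None:
            p.tau_b = float(pc_precision_sample(rng, sp_.pc_u, sp_.pc_alpha))
            p.phi = float(self.phi_prior.sample(rng)) if self.phi_prior else 0.0
            p.u = sample_structured(self.spatial, rng)
            p.v = rng.standard_normal(self.n_areas)
        if sp_.include_temporal and self.temporal is not None:
            p.tau_gamma = float(pc_precision_sample(rng, sp_.pc_u, sp_.pc_alpha))
            p.tau_t = float(pc_precision_sample(rng, sp_.pc_u, sp_.pc_alpha))
            p.w = sample_structured(self.temporal, rng)
            p.z_t = rng.standard_normal(self.n_years)
        if sp_.include_interaction:
            p.tau_st = float(pc_precision_sample(rng, sp_.pc_u, sp_.pc_alpha))
            p.z_st = rng.standard_normal((self.n_areas, self.n_years))
        if sp_.share_scales_free:
            p.delta_s = float(np.exp(sp_.share_log_sd * rng.standard_normal()))
            p.delta_t = float(np.exp(sp_.share_log_sd * rng.standard_normal()))
            p.delta_st = float(np.exp(sp_.share_log_sd * rng.standard_normal()))
        return p

    def _center_u(self, u: np.ndarray) -> None:
        labels = self.graph.component_labels
        for c in np.unique(labels):
            mask = labels == c
            u[mask] -= u[mask].mean()

    # -- densities ----------------------------------------------------
    def log_likelihood(self, params: Params) -> float:
        eta_b, eta_p = linear_predictors(params, self.x, self.E)
        return float(_cell_loglik_eta(self.y, eta_b, eta_p).sum())

    def log_prior(self, params: Params) -> float:
        sp_ = self.spec
        params.validate(self.graph.component_labels if sp_.include_spatial else None)
        lp = 0.0
        for val, sd in (
            (params.alpha_p, sp_.intercept_sd),
            (params.alpha_b, sp_.intercept_sd),
        ):
            lp += _normal_logpdf(val, sd)
        lp += _normal_logpdf(params.beta_p, sp_.beta_sd).sum()
        lp += _normal_logpdf(params.beta_b, sp_.beta_sd).sum()
        if sp_.include_spatial and self.spatial is not None:
            lp += structured_logpdf(params.u, self.spatial)
            lp += _normal_logpdf(params.v, 1.0).sum()
            lp += float(pc_precision_logpdf(params.tau_b, sp_.pc_u, sp_.pc_alpha))
            if self.phi_prior is not None:
                lp += float(self.phi_prior.logpdf(params.phi))
        if sp_.include_temporal and self.temporal is not None:
            lp += structured_logpdf(params.w, self.temporal)
            lp += _normal_logpdf(params.z_t, 1.0).sum()
            lp += float(pc_precision_logpdf(params.tau_gamma, sp_.pc_u, sp_.pc_alpha))
            lp += float(pc_precision_logpdf(params.tau_t, sp_.pc_u, sp_.pc_alpha))
        if sp_.include_interaction:
            lp += _normal_logpdf(params.z_st, 1.0).sum()
            lp += float(pc_precision_logpdf(params.tau_st, sp_.pc_u, sp_.pc_alpha))
        if sp_.share_scales_free:
            for d in (params.delta_s, params.delta_t, params.delta_st):
                if d <= 0:
                    raise ValueError("sharing scales must be positive")
                # lognormal: N(0, share_log_sd) on log delta
                lp += float(_normal_logpdf(np.log(d), sp_.share_log_sd) - np.log(d))
        return float(lp)

    def log_posterior(self, params: Params, likelihood_scale: float = 1.0) -> float:
        return likelihood_scale * self.log_likelihood(params) + self.log_prior(params)


def _normal_logpdf(x, sd: float):
    x = np.asarray(x, dtype=float)
    return -0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def log_posterior(
    params: Params,
    spec: ModelSpec,
    y: np.ndarray,
    E: np.ndarray | ExpectedCounts,
    covariates: np.ndarray | CovariateMatrix,
    graph: AreaGraph,
) -> float:
    """Joint log posterior; convenience wrapper around :class:`HurdleModel`."""
    return HurdleModel(y, E, covariates, graph, spec).log_posterior(params)
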