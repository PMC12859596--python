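"""Posterior summaries: relative risks, exceedance, effects, profiles.

Relative-risk functionals over the posterior draws:

* year level:       RR(t)    = exp(gamma_t + phi_t)
* area level:       RR(i)    = exp(x_i' beta_p + b_i)
* area-year level:  RR(i, t) = exp(x_i' beta_p + b_i + gamma_t + phi_t + psi_it)
* region-year:      expected-count-weighted mean of area-year RRs over
  the areas of a region.

Each unit is summarised by the posterior median, an equal-tailed
credible interval and the exceedance probability P(RR > 1) (strict:
draws exactly at 1 do not exceed).  Exceedance probabilities are banded
into low [0, 0.2], medium (0.2, 0.8] and high (0.8, 1] evidence of
excess risk.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import CovariateMatrix, ExpectedCounts
from .inference import PosteriorSamples

__all__ = [
    "relative_risk",
    "rr_draws",
    "rr_contrast",
    "classify_exceedance",
    "percent_change_per_sd",
    "variance_decomposition",
    "profile_table",
]

logger = logging.getLogger(__name__)

LEVELS = ("year", "area", "area-year", "region-year")


def _x(covariates) -> np.ndarray:
    return covariates.values if isinstance(covariates, CovariateMatrix) \
        else np.asarray(covariates, dtype=float)


def rr_draws(
    samples: PosteriorSamples,
    covariates,
    level: str,
    region_map: np.ndarray | None = None,
    weights: ExpectedCounts | np.ndarray | None = None,
) -> np.ndarray:
    """Per-draw relative risks; leading axis is the pooled draw index."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    gamma = samples.get("gamma", combined=True)
    phi_t = samples.get("phi_t", combined=True)
    if level == "year":
        return np.exp(gamma + phi_t)
    x = _x(covariates)
    beta = samples.get("beta_p", combined=True)  # (D, K)
    b = samples.get("b", combined=True)  # (D, n)
    xb = beta @ x.T  # (D, n)
    if level == "area":
        return np.exp(xb + b)
    psi = samples.get("psi", combined=True)  # (D, n, T)
    log_rr = (
        xb[:, :, None] + b[:, :, None] + (gamma + phi_t)[:, None, :] + psi
    )
    rr = np.exp(log_rr)
    if level == "area-year":
        return rr
    # region-year
    if region_map is None or weights is None:
        raise ValueError("region-year summaries need region_map and weights")
    region_map = np.asarray(region_map)
    e = weights.values if isinstance(weights, ExpectedCounts) else np.asarray(weights, float)
    regions = np.unique(region_map)
    out = np.empty((rr.shape[0], len(regions), rr.shape[2]))
    for r_idx, r in enumerate(regions):
        mask = region_map == r
        w = e[mask]  # (n_r, T)
        out[:, r_idx, :] = (rr[:, mask, :] * w[None]).sum(axis=1) / w.sum(axis=0)[None]
    return out


def _summarise(draws_2d: np.ndarray, cri: float) -> tuple[np.ndarray, ...]:
    lo = (1.0 - cri) / 2.0
    q = np.quantile(draws_2d, [0.5, lo, 1.0 - lo], axis=0)
    exceed = (draws_2d > 1.0).mean(axis=0)
    return q[0], q[1], q[2], exceed


def relative_risk(
    samples: PosteriorSamples,
    covariates,
    level: str,
    region_map: np.ndarray | None = None,
    weights: ExpectedCounts | np.ndarray | None = None,
    area_ids: list | None = None,
    years: list | None = None,
    cri: float = 0.95,
) -> pd.DataFrame:
    """Tidy table of posterior RR summaries at the requested level.

    Columns: the unit keys, then ``median``, ``ci_low``, ``ci_high``,
    ``exceedance`` and the evidence ``category``.
    """
    draws = rr_draws(samples, covariates, level, region_map, weights)
    flat = draws.reshape(draws.shape[0], -1)
    med, lo, hi, exc = _summarise(flat, cri)
    cats = [classify_exceedance(p) for p in exc]
    if level == "year":
        t_n = draws.shape[1]
        years = list(years) if years is not None else list(range(t_n))
        frame = pd.DataFrame({"year": years})
    elif level == "area":
        n = draws.shape[1]
        ids = list(area_ids) if area_ids is not None else list(range(n))
        frame = pd.DataFrame({"area": ids})
    elif level == "area-year":
        n, t_n = draws.shape[1], draws.shape[2]
        ids = list(area_ids) if area_ids is not None else list(range(n))
        yrs = list(years) if years is not None else list(range(t_n))
        frame = pd.DataFrame(
            {"area": np.repeat(ids, t_n), "year": np.tile(yrs, n)}
        )
    else:
        regions = np.unique(np.asarray(region_map))
        t_n = draws.shape[2]
        yrs = list(years) if years is not None else list(range(t_n))
        frame = pd.DataFrame(
            {"region": np.repeat(regions, t_n), "year": np.tile(yrs, len(regions))}
        )
    frame["median"] = med
    frame["ci_low"] = lo
    frame["ci_high"] = hi
    frame["exceedance"] = exc
    frame["category"] = cats
    return frame


def rr_contrast(
    samples: PosteriorSamples,
    covariates,
    level: str,
    unit_a: int,
    unit_b: int,
    region_map: np.ndarray | None = None,
    weights=None,
    cri: float = 0.95,
) -> dict[str, float]:
    """Percent difference of unit_a's RR relative to unit_b's.

    Per draw ``100 * (RR_a / RR_b - 1)``; both units are positions at
    the same summary ``level`` (the shared ``level`` argument makes a
    level mismatch unrepresentable).
    """
    draws = rr_draws(samples, covariates, level, region_map, weights)
    flat = draws.reshape(draws.shape[0], -1)
    n_units = flat.shape[1]
    for u in (unit_a, unit_b):
        if not (0 <= u < n_units):
            raise ValueError(f"unit index {u} outside [0, {n_units})")
    pct = 100.0 * (flat[:, unit_a] / flat[:, unit_b] - 1.0)
    lo = (1.0 - cri) / 2.0
    q = np.quantile(pct, [0.5, lo, 1.0 - lo])
    return {"median": float(q[0]), "ci_low": float(q[1]), "ci_high": float(q[2])}


def classify_exceedance(p: float) -> str:
    """Band an exceedance probability: low [0, .2], medium (.2, .8], high (.8, 1]."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"exceedance probability must lie in [0, 1], got {p}")
    if p <= 0.2:
        return "low"
    if p <= 0.8:
        return "medium"
    return "high"


def percent_change_per_sd(beta_draws: np.ndarray, cri: float = 0.95) -> dict[str, float]:
    """Percent change in risk per one-SD covariate increment.

    Covariates are standardised, so a coefficient is already per-SD;
    the transform is ``100 * (exp(beta) - 1)``.  Quantiles are taken on
    the coefficient scale and then transformed (the transform is
    monotone, so the interval is the equal-tailed credible interval).
    """
    beta_draws = np.asarray(beta_draws, dtype=float).ravel()
    if beta_draws.size == 0:
        raise ValueError("need at least one draw")
    lo = (1.0 - cri) / 2.0
    q = np.quantile(beta_draws, [0.5, lo, 1.0 - lo])
    med, qlo, qhi = 100.0 * np.expm1(q)
    return {"median": float(med), "ci_low": float(qlo), "ci_high": float(qhi)}


def variance_decomposition(
    samples: PosteriorSamples,
    covariates,
    cri: float = 0.95,
    max_excluded_frac: float = 0.5,
) -> pd.DataFrame:
    """Share of RR variability attributed to each model component.

    Per draw, the empirical variance over all (area, year) units of the
    covariate contribution, the spatial effect, the temporal effect and
    the interaction, each divided by the variance of the total non-offset
    linear predictor.  Components may covary, so shares need not sum to
    100.  Draws with zero total variance are excluded (error if more
    than ``max_excluded_frac`` of draws would be dropped).
    """
    x = _x(covariates)
    beta = samples.get("beta_p", combined=True)
    b = samples.get("b", combined=True)
    gamma = samples.get("gamma", combined=True)
    phi_t = samples.get("phi_t", combined=True)
    psi = samples.get("psi", combined=True)
    n_draws, n, t = psi.shape

    xb = beta @ x.T  # (D, n)
    temporal = gamma + phi_t  # (D, T)
    shares = {k: [] for k in ("covariates", "spatial", "temporal", "spatio-temporal")}
    excluded = 0
    for d in range(n_draws):
        cov_f = np.broadcast_to(xb[d][:, None], (n, t))
        sp_f = np.broadcast_to(b[d][:, None], (n, t))
        tm_f = np.broadcast_to(temporal[d][None, :], (n, t))
        st_f = psi[d]
        total = cov_f + sp_f + tm_f + st_f
        v_tot = total.var()
        if v_tot == 0.0:
            excluded += 1
            continue
        shares["covariates"].append(100.0 * cov_f.var() / v_tot)
        shares["spatial"].append(100.0 * sp_f.var() / v_tot)
        shares["temporal"].append(100.0 * tm_f.var() / v_tot)
        shares["spatio-temporal"].append(100.0 * st_f.var() / v_tot)
    if excluded:
        logger.info("variance_decomposition: excluded %d zero-variance draws", excluded)
    if excluded > max_excluded_frac * n_draws:
        raise ValueError(
            f"{excluded}/{n_draws} draws had zero total variance; shares undefined"
        )
    lo = (1.0 - cri) / 2.0
    rows = []
    for comp, vals in shares.items():
        q = np.quantile(np.asarray(vals), [0.5, lo, 1.0 - lo])
        rows.append((comp, q[0], q[1], q[2]))
    return pd.DataFrame(rows, columns=["component", "median", "ci_low", "ci_high"])


def profile_table(
    rr_area_year: pd.DataFrame,
    covariates: CovariateMatrix,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Mean covariate score per percentile of area-year relative risk.

    Units (area-year rows of ``rr_area_year``, as produced by
    :func:`relative_risk` at the area-year level) are ranked by their
    median RR ascending, ties broken by stable unit order, and split
    into ``n_bins`` near-equal bins; each bin reports the mean of every
    standardised covariate (area-level values broadcast across years)
    and the mean median RR.
    """
    x = _x(covariates)
    names = covariates.names if isinstance(covariates, CovariateMatrix) \
        else [f"cov{j + 1}" for j in range(x.shape[1])]
    df = rr_area_year.reset_index(drop=True)
    if "area" not in df.columns or "median" not in df.columns:
        raise ValueError("rr_area_year must have 'area' and 'median' columns")
    n_units = len(df)
    bins = min(n_bins, n_units)
    if bins < n_bins:
        logger.info("profile_table: only %d units; using %d bins", n_units, bins)
    area_codes, _ = pd.factorize(df["area"], sort=True)
    order = np.lexsort((np.arange(n_units), df["median"].to_numpy()))
    chunks = np.array_split(order, bins)
    rows = []
    for p, chunk in enumerate(chunks, start=1):
        means = x[area_codes[chunk]].mean(axis=0)
        rows.append((p, float(df["median"].to_numpy()[chunk].mean()), *means))
    return pd.DataFrame(rows, columns=["percentile", "mean_median_rr", *names])
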