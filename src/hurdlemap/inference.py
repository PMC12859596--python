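"""Posterior sampling by blocked adaptive Metropolis-within-Gibbs.

The sampler exploits the Markov structure of the latent fields:

* fixed effects are updated in two blocks, (alpha_p, beta_p) and
  (alpha_b, beta_b), with adaptive Gaussian random-walk proposals
  targeting ~0.23 acceptance;
* latent fields are updated site-wise with per-site adaptive step sizes
  targeting ~0.44 acceptance.  Sites whose full conditionals are
  mutually independent are updated simultaneously: the iid fields
  (unstructured spatial, exchangeable temporal, interaction) in one
  vectorised sweep, the structured fields over the colour classes of a
  greedy graph colouring (no two neighbours in a class);
* hyperparameters (precisions, BYM2 mixing, sharing scales) use scalar
  random walks on the log / logit scale.

Sum-to-zero constraints on the structured fields are enforced by
re-centring (per graph component, and over years for the random walk)
once per sweep, after which all caches are rebuilt from the parameter
state.  All randomness flows from a single integer seed; chains use
independent substreams and runs are bit-reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .data import CovariateMatrix, ExpectedCounts
from .graph import AreaGraph
from .model import HurdleModel, ModelSpec, Params, _cell_loglik_eta
from .priors import pc_precision_logpdf

__all__ = ["PosteriorSamples", "run_mcmc", "convergence_diagnostics", "DiagnosticsReport"]

_STORED = [
    "alpha_p", "alpha_b", "beta_p", "beta_b", "b", "gamma", "phi_t", "psi",
    "tau_b", "phi", "tau_gamma", "tau_t", "tau_st",
    "delta_s", "delta_t", "delta_st", "lp",
]


@dataclass
class PosteriorSamples:
    """Draws of all model quantities, shaped ``(n_chains, n_draws, ...)``."""

    draws: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws["alpha_p"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["alpha_p"].shape[1]

    def get(self, name: str, combined: bool = False) -> np.ndarray:
        arr = self.draws[name]
        if combined:
            return arr.reshape(-1, *arr.shape[2:])
        return arr

    # -- persistence (per-parameter columnar CSV + manifest) ----------
    def save(self, directory) -> None:
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        shapes = {}
        for name, arr in self.draws.items():
            shapes[name] = list(arr.shape)
            flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
            np.savetxt(directory / f"{name}.csv", flat, delimiter=",", fmt="%.17g")
        manifest = {"shapes": shapes, "meta": _jsonable(self.meta)}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        import json
        from pathlib import Path

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        draws = {}
        for name, shape in manifest["shapes"].items():
            flat = np.loadtxt(directory / f"{name}.csv", delimiter=",", ndmin=2)
            draws[name] = flat.reshape(shape)
        return cls(draws, manifest.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------
# single-chain sampler
# ---------------------------------------------------------------------

class _ChainSampler:
    def __init__(
        self,
        model: HurdleModel,
        rng: np.random.Generator,
        likelihood_scale: float = 1.0,
    ) -> None:
        self.m = model
        self.rng = rng
        self.lscale = likelihood_scale
        self.spec = model.spec
        n, t = model.n_areas, model.n_years

        self.p = model.init_params(rng)
        # colour classes for structured fields
        if self.spec.include_spatial and model.graph.n_edges:
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(map(tuple, model.graph.edges))
            colours = nx.greedy_color(g, strategy="largest_first")
            n_col = max(colours.values()) + 1
            self.u_classes = [
                np.array([i for i in range(n) if colours[i] == c], dtype=np.int64)
                for c in range(n_col)
            ]
            self.q_diag = model.spatial.Q.diagonal()
        else:
            self.u_classes = []
            self.q_diag = np.zeros(n)
        self.w_classes = (
            [np.arange(0, t, 2), np.arange(1, t, 2)]
            if self.spec.include_temporal
            else []
        )
        self.w_diag = model.temporal.Q.diagonal() if model.temporal is not None else None

        # adaptation state
        self.log_s_block = {"p": np.log(0.1), "b": np.log(0.1), "x": np.log(0.1)}
        self.block_welford = {
            "p": _Welford(1 + model.k),
            "b": _Welford(1 + model.k),
        }
        self.log_step_u = np.full(n, np.log(0.5))
        self.log_step_v = np.full(n, np.log(0.5))
        self.log_step_w = np.full(t, np.log(0.5))
        self.log_step_zt = np.full(t, np.log(0.5))
        self.log_step_zst = np.full((n, t), np.log(0.5))
        self.log_step_hyper = {
            k: np.log(0.5)
            for k in ("tau_b", "phi", "tau_gamma", "tau_t", "tau_st",
                      "delta_s", "delta_t", "delta_st")
        }
        self.accept_counts: dict[str, float] = {}
        self.update_counts: dict[str, float] = {}

        self._rebuild()

    # -- caches --------------------------------------------------------
    def _cells(self, y, eta_b, eta_p):
        if self.lscale == 0.0:
            return np.zeros(np.broadcast_shapes(eta_b.shape, eta_p.shape))
        return self.lscale * _cell_loglik_eta(y, eta_b, eta_p)

    def _compose_eta(self, p: Params):
        m = self.m
        b = p.b
        gam = p.gamma + p.phi_t
        psi = p.psi
        eta_p = (
            m.log_e + p.alpha_p + self.xbp[:, None] + b[:, None]
            + gam[None, :] + psi
        )
        eta_b = (
            p.alpha_b + self.xbb[:, None] + p.delta_s * b[:, None]
            + p.delta_t * gam[None, :] + p.delta_st * psi
        )
        return eta_b, eta_p, b, gam, psi

    def _rebuild(self) -> None:
        p, m = self.p, self.m
        self.xbp = m.x @ p.beta_p
        self.xbb = m.x @ p.beta_b
        self.eta_b, self.eta_p, self.b, self.gam, self.psi = self._compose_eta(p)
        self.L = self._cells(m.y, self.eta_b, self.eta_p)
        self.ll = float(self.L.sum())

    # -- bookkeeping ---------------------------------------------------
    def _tally(self, name: str, accepted: float, total: float) -> None:
        self.accept_counts[name] = self.accept_counts.get(name, 0.0) + accepted
        self.update_counts[name] = self.update_counts.get(name, 0.0) + total

    @staticmethod
    def _adapt_rate(it: int) -> float:
        return (it + 1) ** -0.6

    # -- fixed-effect blocks -------------------------------------------
    def _update_block(self, which: str, it: int, adapt: bool) -> None:
        p, m = self.p, self.m
        wf = self.block_welford[which]
        dim = 1 + m.k
        sd = wf.sd() if wf.count > 100 else np.full(dim, 1.0)
        step = np.exp(self.log_s_block[which]) / np.sqrt(dim)
        d = step * sd * self.rng.standard_normal(dim)
        if which == "p":
            theta_old = np.concatenate([[p.alpha_p], p.beta_p])
            eta_new = self.eta_p + d[0] + (m.x @ d[1:])[:, None]
            l_new = self._cells(m.y, self.eta_b, eta_new)
        else:
            theta_old = np.concatenate([[p.alpha_b], p.beta_b])
            eta_new = self.eta_b + d[0] + (m.x @ d[1:])[:, None]
            l_new = self._cells(m.y, eta_new, self.eta_p)
        theta_new = theta_old + d
        sds = np.concatenate([[self.spec.intercept_sd],
                              np.full(m.k, self.spec.beta_sd)])
        dprior = -0.5 * float(np.sum((theta_new / sds) ** 2 - (theta_old / sds) ** 2))
        dll = float(l_new.sum()) - self.ll
        accept = np.log(self.rng.random()) < dll + dprior
        if accept:
            if which == "p":
                p.alpha_p += d[0]
                p.beta_p = p.beta_p + d[1:]
                self.xbp = m.x @ p.beta_p
                self.eta_p = eta_new
            else:
                p.alpha_b += d[0]
                p.beta_b = p.beta_b + d[1:]
                self.xbb = m.x @ p.beta_b
                self.eta_b = eta_new
            self.L = l_new
            self.ll = float(l_new.sum())
        if adapt:
            r = self._adapt_rate(it)
            self.log_s_block[which] += r * ((1.0 if accept else 0.0) - 0.23)
            wf.push(np.concatenate([[p.alpha_p], p.beta_p]) if which == "p"
                    else np.concatenate([[p.alpha_b], p.beta_b]))
        self._tally(f"block_{which}", float(accept), 1.0)

    def _update_beta_spatial_exchange(self, it: int, adapt: bool) -> None:
        """Joint move along the spatial-confounding direction.

        Shifts (alpha_p, beta_p) and compensates through the unstructured
        spatial component so that eta_p is unchanged: b' = b - (d0 + X d),
        v' = v + sqrt(tau_b / (1 - phi)) * (b' - b).  Only the gate
        likelihood (through the shared b) and the priors enter the
        acceptance ratio, which decorrelates the coefficients from the
        spatial field when covariates are themselves spatially smooth.
        """
        p, m = self.p, self.m
        if p.phi > 0.995:
            return
        dim = 1 + m.k
        wf = self.block_welford["p"]
        sd = wf.sd() if wf.count > 100 else np.full(dim, 1.0)
        step = np.exp(self.log_s_block["x"]) / np.sqrt(dim)
        d = step * sd * self.rng.standard_normal(dim)
        shift = d[0] + m.x @ d[1:]  # change in alpha_p + x' beta_p per area
        dv = -shift * np.sqrt(p.tau_b / (1.0 - p.phi))
        eta_b_new = self.eta_b - p.delta_s * shift[:, None]
        l_new = self._cells(m.y, eta_b_new, self.eta_p)
        dprior = -0.5 * float(((p.v + dv) ** 2 - p.v**2).sum())
        theta_old = np.concatenate([[p.alpha_p], p.beta_p])
        sds = np.concatenate([[self.spec.intercept_sd],
                              np.full(m.k, self.spec.beta_sd)])
        dprior += -0.5 * float(np.sum(((theta_old + d) / sds) ** 2
                                      - (theta_old / sds) ** 2))
        dll = float(l_new.sum()) - self.ll
        accept = np.log(self.rng.random()) < dll + dprior
        if accept:
            p.alpha_p += d[0]
            p.beta_p = p.beta_p + d[1:]
            p.v = p.v + dv
            self.xbp = m.x @ p.beta_p
            self.b = self.b - shift
            self.eta_b = eta_b_new
            self.L = l_new
            self.ll = float(l_new.sum())
        if adapt:
            r = self._adapt_rate(it)
            self.log_s_block["x"] += r * ((1.0 if accept else 0.0) - 0.23)
        self._tally("beta_exchange", float(accept), 1.0)

    def _update_gate_exchange(self, it: int, adapt: bool) -> None:
        """Likelihood-invariant move for the gate coefficients.

        Shifts (alpha_b, beta_b) by d, moves the spatial field so the
        gate predictor is unchanged (b' = b - (d0 + X d)/delta_s via the
        unstructured component), and counter-shifts (alpha_p, beta_p) by
        d/delta_s so the count predictor is unchanged too.  Both
        likelihood components are invariant; only the Gaussian priors
        enter the ratio.  Decorrelates the gate coefficients from the
        shared spatial field.
        """
        p, m = self.p, self.m
        if p.phi > 0.995 or abs(p.delta_s) < 0.05:
            return
        dim = 1 + m.k
        wf = self.block_welford["b"]
        sd = wf.sd() if wf.count > 100 else np.full(dim, 1.0)
        if "g" not in self.log_s_block:
            self.log_s_block["g"] = np.log(0.1)
        step = np.exp(self.log_s_block["g"]) / np.sqrt(dim)
        d = step * sd * self.rng.standard_normal(dim)
        shift = (d[0] + m.x @ d[1:]) / p.delta_s  # change pushed into b
        dv = -shift * np.sqrt(p.tau_b / (1.0 - p.phi))
        sds = np.concatenate([[self.spec.intercept_sd],
                              np.full(m.k, self.spec.beta_sd)])
        th_b = np.concatenate([[p.alpha_b], p.beta_b])
        th_p = np.concatenate([[p.alpha_p], p.beta_p])
        dp = d / p.delta_s
        dprior = -0.5 * float(((p.v + dv) ** 2 - p.v**2).sum())
        dprior += -0.5 * float(np.sum(((th_b + d) / sds) ** 2 - (th_b / sds) ** 2))
        dprior += -0.5 * float(np.sum(((th_p + dp) / sds) ** 2 - (th_p / sds) ** 2))
        accept = np.log(self.rng.random()) < dprior
        if accept:
            p.alpha_b += d[0]
            p.beta_b = p.beta_b + d[1:]
            p.alpha_p += dp[0]
            p.beta_p = p.beta_p + dp[1:]
            p.v = p.v + dv
            self.xbp = m.x @ p.beta_p
            self.xbb = m.x @ p.beta_b
            self.b = self.b - shift
        if adapt:
            r = self._adapt_rate(it)
            self.log_s_block["g"] += r * ((1.0 if accept else 0.0) - 0.23)
        self._tally("gate_exchange", float(accept), 1.0)

    # -- site-wise field updates ---------------------------------------
    def _row_update(self, rows, db, name, log_step, dx, prior_delta, apply_fn, it, adapt):
        """Generic accept/reject for per-area proposals affecting whole rows."""
        m = self.m
        eb = self.eta_b[rows] + self._db_eta_b(db)[:, None]
        ep = self.eta_p[rows] + db[:, None]
        l_new = self._cells(m.y[rows], eb, ep)
        dll = (l_new - self.L[rows]).sum(axis=1)
        acc = np.log(self.rng.random(len(rows))) < dll + prior_delta
        if acc.any():
            sel = rows[acc]
            apply_fn(sel, dx[acc], db[acc])
            self.eta_b[sel] = eb[acc]
            self.eta_p[sel] = ep[acc]
            self.L[sel] = l_new[acc]
            self.ll = float(self.L.sum())
        if adapt:
            r = self._adapt_rate(it)
            log_step[rows] += r * (acc.astype(float) - 0.44)
        self._tally(name, float(acc.sum()), float(len(rows)))

    def _db_eta_b(self, db):
        return self.p.delta_s * db

    def _update_u(self, it: int, adapt: bool) -> None:
        p, m = self.p, self.m
        scale_b = np.sqrt(p.phi / p.tau_b)
        g = m.spatial.scaling
        for rows in self.u_classes:
            qu = m.spatial.Q @ p.u
            du = np.exp(self.log_step_u[rows]) * self.rng.standard_normal(len(rows))
            db = scale_b * du
            dprior = -g * (du * qu[rows] + 0.5 * self.q_diag[rows] * du**2)

            def apply(sel, dx, dbv):
                p.u[sel] += dx
                self.b[sel] += dbv

            self._row_update(rows, db, "u", self.log_step_u, du, dprior, apply, it, adapt)

    def _update_v(self, it: int, adapt: bool) -> None:
        p = self.p
        n = self.m.n_areas
        rows = np.arange(n)
        scale_b = np.sqrt((1.0 - p.phi) / p.tau_b)
        dv = np.exp(self.log_step_v) * self.rng.standard_normal(n)
        db = scale_b * dv
        dprior = -(p.v * dv + 0.5 * dv**2)

        def apply(sel, dx, dbv):
            p.v[sel] += dx
            self.b[sel] += dbv

        self._row_update(rows, db, "v", self.log_step_v, dv, dprior, apply, it, adapt)

    def _col_update(self, cols, dgam, name, log_step, dx, prior_delta, apply_fn, it, adapt):
        m = self.m
        eb = self.eta_b[:, cols] + self.p.delta_t * dgam[None, :]
        ep = self.eta_p[:, cols] + dgam[None, :]
        l_new = self._cells(m.y[:, cols], eb, ep)
        dll = (l_new - self.L[:, cols]).sum(axis=0)
        acc = np.log(self.rng.random(len(cols))) < dll + prior_delta
        if acc.any():
            sel = cols[acc]
            apply_fn(sel, dx[acc], dgam[acc])
            self.eta_b[:, sel] = eb[:, acc]
            self.eta_p[:, sel] = ep[:, acc]
            self.L[:, sel] = l_new[:, acc]
            self.ll = float(self.L.sum())
        if adapt:
            r = self._adapt_rate(it)
            log_step[cols] += r * (acc.astype(float) - 0.44)
        self._tally(name, float(acc.sum()), float(len(cols)))

    def _update_w(self, it: int, adapt: bool) -> None:
        p, m = self.p, self.m
        scale = 1.0 / np.sqrt(p.tau_gamma)
        g = m.temporal.scaling
        for cols in self.w_classes:
            if not len(cols):
                continue
            qw = m.temporal.Q @ p.w
            dw = np.exp(self.log_step_w[cols]) * self.rng.standard_normal(len(cols))
            dg = scale * dw
            dprior = -g * (dw * qw[cols] + 0.5 * self.w_diag[cols] * dw**2)

            def apply(sel, dx, dgv):
                p.w[sel] += dx
                self.gam[sel] += dgv

            self._col_update(cols, dg, "w", self.log_step_w, dw, dprior, apply, it, adapt)

    def _update_zt(self, it: int, adapt: bool) -> None:
        p = self.p
        t = self.m.n_years
        cols = np.arange(t)
        scale = 1.0 / np.sqrt(p.tau_t)
        dz = np.exp(self.log_step_zt) * self.rng.standard_normal(t)
        dg = scale * dz
        dprior = -(p.z_t * dz + 0.5 * dz**2)

        def apply(sel, dx, dgv):
            p.z_t[sel] += dx
            self.gam[sel] += dgv

        self._col_update(cols, dg, "z_t", self.log_step_zt, dz, dprior, apply, it, adapt)

    def _update_zst(self, it: int, adapt: bool) -> None:
        p, m = self.p, self.m
        scale = 1.0 / np.sqrt(p.tau_st)
        dz = np.exp(self.log_step_zst) * self.rng.standard_normal(p.z_st.shape)
        dpsi = scale * dz
        eb = self.eta_b + p.delta_st * dpsi
        ep = self.eta_p + dpsi
        l_new = self._cells(m.y, eb, ep)
        dll = l_new - self.L
        dprior = -(p.z_st * dz + 0.5 * dz**2)
        acc = np.log(self.rng.random(dz.shape)) < dll + dprior
        if acc.any():
            p.z_st[acc] += dz[acc]
            self.psi[acc] += dpsi[acc]
            self.eta_b[acc] = eb[acc]
            self.eta_p[acc] = ep[acc]
            self.L[acc] = l_new[acc]
            self.ll = float(self.L.sum())
        if adapt:
            r = self._adapt_rate(it)
            self.log_step_zst += r * (acc.astype(float) - 0.44)
        self._tally("z_st", float(acc.sum()), float(acc.size))

    # -- hyperparameters -----------------------------------------------
    def _hyper_logprior(self, p: Params) -> dict[str, float]:
        sp_ = self.spec
        out = {}
        if sp_.include_spatial and self.m.spatial is not None:
            # include the log-scale Jacobian for the random walk on log tau
            out["tau_b"] = float(
                pc_precision_logpdf(p.tau_b, sp_.pc_u, sp_.pc_alpha) + np.log(p.tau_b)
            )
            if self.m.phi_prior is not None:
                ph = p.phi
                out["phi"] = float(
                    self.m.phi_prior.logpdf(ph) + np.log(ph) + np.log1p(-ph)
                )
        if sp_.include_temporal:
            out["tau_gamma"] = float(
                pc_precision_logpdf(p.tau_gamma, sp_.pc_u, sp_.pc_alpha)
                + np.log(p.tau_gamma)
            )
            out["tau_t"] = float(
                pc_precision_logpdf(p.tau_t, sp_.pc_u, sp_.pc_alpha) + np.log(p.tau_t)
            )
        if sp_.include_interaction:
            out["tau_st"] = float(
                pc_precision_logpdf(p.tau_st, sp_.pc_u, sp_.pc_alpha) + np.log(p.tau_st)
            )
        if sp_.share_scales_free:
            for nm in ("delta_s", "delta_t", "delta_st"):
                d = getattr(p, nm)
                # RW on log delta, whose prior is N(0, share_log_sd)
                out[nm] = float(-0.5 * (np.log(d) / sp_.share_log_sd) ** 2)
        return out

    def _update_hyper(self, name: str, it: int, adapt: bool) -> None:
        p = self.p
        current = getattr(p, name)
        if name == "phi":
            theta = np.log(current) - np.log1p(-current)
        else:
            theta = np.log(current)
        step = np.exp(self.log_step_hyper[name])
        theta_new = theta + step * self.rng.standard_normal()
        proposal = p.copy()
        if name == "phi":
            setattr(proposal, name, float(1.0 / (1.0 + np.exp(-theta_new))))
        else:
            setattr(proposal, name, float(np.exp(theta_new)))
        eta_b_new, eta_p_new, b_new, gam_new, psi_new = self._compose_eta(proposal)
        l_new = self._cells(self.m.y, eta_b_new, eta_p_new)
        lp_old = self._hyper_logprior(p).get(name, 0.0)
        lp_new = self._hyper_logprior(proposal).get(name, 0.0)
        dpost = float(l_new.sum()) - self.ll + lp_new - lp_old
        accept = np.log(self.rng.random()) < dpost
        if accept:
            setattr(p, name, getattr(proposal, name))
            self.eta_b, self.eta_p = eta_b_new, eta_p_new
            self.b, self.gam, self.psi = b_new, gam_new, psi_new
            self.L = l_new
            self.ll = float(l_new.sum())
        if adapt:
            r = self._adapt_rate(it)
            self.log_step_hyper[name] += r * ((1.0 if accept else 0.0) - 0.44)
        self._tally(name, float(accept), 1.0)

    def _update_tau_rescale(self, name: str, it: int, adapt: bool) -> None:
        """Likelihood-invariant precision move (interweaving).

        Proposes tau' = c tau while rescaling the standardised field(s)
        by sqrt(c) so the composite effect is unchanged; the ratio
        involves only the field priors, the PC prior and the Jacobians.
        Complements the plain random-walk update, which struggles when
        the likelihood pins the composite field tightly.
        """
        p, m = self.p, self.m
        key = f"{name}_rescale"
        if key not in self.log_step_hyper:
            self.log_step_hyper[key] = np.log(0.5)
        eps = np.exp(self.log_step_hyper[key]) * self.rng.standard_normal()
        c = float(np.exp(eps))
        tau_old = getattr(p, name)
        tau_new = tau_old * c
        sp_ = self.spec
        if name == "tau_b":
            quad = float(p.v @ p.v) + m.spatial.scaling * float(p.u @ (m.spatial.Q @ p.u))
            dim = 2 * m.n_areas
        elif name == "tau_gamma":
            quad = m.temporal.scaling * float(p.w @ (m.temporal.Q @ p.w))
            dim = m.n_years
        elif name == "tau_t":
            quad = float(p.z_t @ p.z_t)
            dim = m.n_years
        else:  # tau_st
            quad = float((p.z_st**2).sum())
            dim = p.z_st.size
        log_ratio = (
            -0.5 * (c - 1.0) * quad
            + float(pc_precision_logpdf(tau_new, sp_.pc_u, sp_.pc_alpha))
            + np.log(tau_new)
            - float(pc_precision_logpdf(tau_old, sp_.pc_u, sp_.pc_alpha))
            - np.log(tau_old)
            + 0.5 * dim * np.log(c)
        )
        accept = np.log(self.rng.random()) < log_ratio
        if accept:
            root = np.sqrt(c)
            setattr(p, name, tau_new)
            if name == "tau_b":
                p.u *= root
                p.v *= root
            elif name == "tau_gamma":
                p.w *= root
            elif name == "tau_t":
                p.z_t *= root
            else:
                p.z_st *= root
        if adapt:
            r = self._adapt_rate(it)
            self.log_step_hyper[key] += r * ((1.0 if accept else 0.0) - 0.44)
        self._tally(key, float(accept), 1.0)

    def _update_shared_rescale(self, which: str, it: int, adapt: bool) -> None:
        """Joint (precision, sharing-scale) move along the gate ridge.

        The gate sees delta * field while the count component sees the
        field alone; when the count data are sparse the two trade off
        along a long ridge.  Propose tau' = c tau (field shrinks by
        sqrt(c)) together with delta' = delta sqrt(c), leaving the gate
        contribution invariant; only the count likelihood and the
        hyperpriors enter the ratio.
        """
        p, m = self.p, self.m
        key = f"share_{which}"
        if key not in self.log_step_hyper:
            self.log_step_hyper[key] = np.log(0.5)
        eps = np.exp(self.log_step_hyper[key]) * self.rng.standard_normal()
        c = float(np.exp(eps))
        root = np.sqrt(c)
        sp_ = self.spec
        proposal = p.copy()
        if which == "spatial":
            proposal.tau_b = p.tau_b * c
            proposal.delta_s = p.delta_s * root
            taus = [("tau_b", p.tau_b, proposal.tau_b)]
            d_old, d_new = p.delta_s, proposal.delta_s
        elif which == "temporal":
            proposal.tau_gamma = p.tau_gamma * c
            proposal.tau_t = p.tau_t * c
            proposal.delta_t = p.delta_t * root
            taus = [("tau_gamma", p.tau_gamma, proposal.tau_gamma),
                    ("tau_t", p.tau_t, proposal.tau_t)]
            d_old, d_new = p.delta_t, proposal.delta_t
        else:  # interaction
            proposal.tau_st = p.tau_st * c
            proposal.delta_st = p.delta_st * root
            taus = [("tau_st", p.tau_st, proposal.tau_st)]
            d_old, d_new = p.delta_st, proposal.delta_st
        eta_b_new, eta_p_new, b_new, gam_new, psi_new = self._compose_eta(proposal)
        l_new = self._cells(m.y, eta_b_new, eta_p_new)
        log_ratio = float(l_new.sum()) - self.ll
        for _, old, new in taus:
            log_ratio += float(
                pc_precision_logpdf(new, sp_.pc_u, sp_.pc_alpha) + np.log(new)
                - pc_precision_logpdf(old, sp_.pc_u, sp_.pc_alpha) - np.log(old)
            )
        sd = sp_.share_log_sd
        log_ratio += -0.5 * (np.log(d_new) / sd) ** 2 + 0.5 * (np.log(d_old) / sd) ** 2
        accept = np.log(self.rng.random()) < log_ratio
        if accept:
            for name, _, new in taus:
                setattr(p, name, new)
            if which == "spatial":
                p.delta_s = d_new
            elif which == "temporal":
                p.delta_t = d_new
            else:
                p.delta_st = d_new
            self.eta_b, self.eta_p = eta_b_new, eta_p_new
            self.b, self.gam, self.psi = b_new, gam_new, psi_new
            self.L = l_new
            self.ll = float(l_new.sum())
        if adapt:
            r = self._adapt_rate(it)
            self.log_step_hyper[key] += r * ((1.0 if accept else 0.0) - 0.23)
        self._tally(key, float(accept), 1.0)

    # -- sweep ----------------------------------------------------------
    def _recenter(self) -> None:
        p, m = self.p, self.m
        if self.spec.include_spatial:
            m._center_u(p.u)
        if self.spec.include_temporal:
            p.w -= p.w.mean()
        self._rebuild()

    def sweep(self, it: int, adapt: bool) -> None:
        sp_ = self.spec
        self._update_block("p", it, adapt)
        self._update_block("b", it, adapt)
        if sp_.include_spatial and self.m.spatial is not None:
            self._update_u(it, adapt)
            self._update_v(it, adapt)
            self._update_beta_spatial_exchange(it, adapt)
            self._update_gate_exchange(it, adapt)
            self._update_hyper("tau_b", it, adapt)
            self._update_tau_rescale("tau_b", it, adapt)
            if self.m.phi_prior is not None:
                self._update_hyper("phi", it, adapt)
        if sp_.include_temporal and self.m.temporal is not None:
            self._update_w(it, adapt)
            self._update_zt(it, adapt)
            self._update_hyper("tau_gamma", it, adapt)
            self._update_tau_rescale("tau_gamma", it, adapt)
            self._update_hyper("tau_t", it, adapt)
            self._update_tau_rescale("tau_t", it, adapt)
        if sp_.include_interaction:
            self._update_zst(it, adapt)
            self._update_hyper("tau_st", it, adapt)
            self._update_tau_rescale("tau_st", it, adapt)
        if sp_.share_scales_free:
            if sp_.include_spatial:
                self._update_hyper("delta_s", it, adapt)
                self._update_shared_rescale("spatial", it, adapt)
            if sp_.include_temporal:
                self._update_hyper("delta_t", it, adapt)
                self._update_shared_rescale("temporal", it, adapt)
            if sp_.include_interaction:
                self._update_hyper("delta_st", it, adapt)
                self._update_shared_rescale("interaction", it, adapt)
        self._recenter()
        if not np.isfinite(self.ll):
            raise FloatingPointError(
                "non-finite likelihood during sampling; state: "
                f"alpha_p={self.p.alpha_p:.3g}, alpha_b={self.p.alpha_b:.3g}, "
                f"max|eta_p|={np.abs(self.eta_p).max():.3g}"
            )

    def run(self, n_iter: int, n_warmup: int, thin: int) -> dict[str, np.ndarray]:
        m = self.m
        kept = max(0, -((n_iter - n_warmup) // -thin))
        store: dict[str, list] = {k: [] for k in _STORED}
        for it in range(n_iter):
            self.sweep(it, adapt=it < n_warmup)
            if it >= n_warmup and (it - n_warmup) % thin == 0:
                p = self.p
                store["alpha_p"].append(p.alpha_p)
                store["alpha_b"].append(p.alpha_b)
                store["beta_p"].append(p.beta_p.copy())
                store["beta_b"].append(p.beta_b.copy())
                store["b"].append(p.b)
                store["gamma"].append(p.gamma)
                store["phi_t"].append(p.phi_t)
                store["psi"].append(p.psi)
                store["tau_b"].append(p.tau_b)
                store["phi"].append(p.phi)
                store["tau_gamma"].append(p.tau_gamma)
                store["tau_t"].append(p.tau_t)
                store["tau_st"].append(p.tau_st)
                store["delta_s"].append(p.delta_s)
                store["delta_t"].append(p.delta_t)
                store["delta_st"].append(p.delta_st)
                store["lp"].append(self.ll / max(self.lscale, 1e-300) * (self.lscale != 0)
                                   + m.log_prior(p))
        out = {k: np.asarray(v) for k, v in store.items()}
        assert out["alpha_p"].shape[0] == kept
        return out


class _Welford:
    """Running mean/variance for adapting block proposal shapes."""

    def __init__(self, dim: int) -> None:
        self.count = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x: np.ndarray) -> None:
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += delta * (x - self.mean)

    def sd(self) -> np.ndarray:
        if self.count < 2:
            return np.ones_like(self.mean)
        return np.sqrt(self.m2 / (self.count - 1)) + 1e-6


# ---------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------

def run_mcmc(
    y: np.ndarray,
    E: np.ndarray | ExpectedCounts,
    covariates: np.ndarray | CovariateMatrix,
    graph: AreaGraph,
    spec: ModelSpec | None = None,
    n_chains: int = 4,
    n_iter: int = 5000,
    n_warmup: int = 2500,
    seed: int = 0,
    thin: int = 1,
    likelihood_scale: float = 1.0,
) -> PosteriorSamples:
    """Draw posterior samples of the full latent state.

    Chains run sequentially on independent seed substreams; the result
    is a deterministic function of the inputs and ``seed``.  Set
    ``likelihood_scale=0.0`` for a prior-only run.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if not (0 <= n_warmup < n_iter):
        raise ValueError("need 0 <= n_warmup < n_iter")
    model = HurdleModel(y, E, covariates, graph, spec)
    t0 = time.time()
    chains = []
    accept = []
    for c in range(n_chains):
        rng = np.random.default_rng([int(seed), c])
        sampler = _ChainSampler(model, rng, likelihood_scale)
        chains.append(sampler.run(n_iter, n_warmup, thin))
        accept.append({
            k: sampler.accept_counts[k] / max(sampler.update_counts[k], 1.0)
            for k in sampler.accept_counts
        })
    draws = {k: np.stack([c[k] for c in chains]) for k in _STORED}
    meta = {
        "seed": int(seed),
        "n_chains": n_chains,
        "n_iter": n_iter,
        "n_warmup": n_warmup,
        "thin": thin,
        "likelihood_scale": likelihood_scale,
        "runtime_s": time.time() - t0,
        "acceptance": accept,
        "spec": model.spec.to_dict(),
    }
    return PosteriorSamples(draws, meta)


# ---------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    table: "object"  # pandas DataFrame: parameter, rhat, ess
    passed: bool
    max_rhat: float
    min_ess: float
    degenerate: list

    def __repr__(self) -> str:
        return (
            f"DiagnosticsReport(passed={self.passed}, max_rhat={self.max_rhat:.4f}, "
            f"min_ess={self.min_ess:.1f}, degenerate={self.degenerate})"
        )


def convergence_diagnostics(
    samples: PosteriorSamples,
    rhat_threshold: float = 1.05,
    n_latent: int = 5,
    seed: int = 0,
) -> DiagnosticsReport:
    """Split-R-hat and effective sample size for the monitored scalars.

    Monitors intercepts, covariate coefficients, hyperparameters and a
    seeded random subset of latent effects.  Chains that are exactly
    constant are flagged as degenerate rather than failing numerically.
    """
    import arviz as az
    import pandas as pd

    if samples.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    if samples.n_draws < 100:
        raise ValueError("diagnostics require at least 100 post-warmup draws")

    rng = np.random.default_rng(seed)
    scalars: dict[str, np.ndarray] = {}
    for name in ("alpha_p", "alpha_b", "tau_b", "phi", "tau_gamma", "tau_t",
                 "tau_st", "delta_s", "delta_t", "delta_st", "lp"):
        if name in samples.draws:
            scalars[name] = samples.draws[name]
    for name in ("beta_p", "beta_b"):
        arr = samples.draws.get(name)
        if arr is not None and arr.ndim == 3:
            for j in range(arr.shape[2]):
                scalars[f"{name}[{j}]"] = arr[:, :, j]
    for name in ("b", "gamma", "phi_t"):
        arr = samples.draws.get(name)
        if arr is not None and arr.ndim == 3 and arr.shape[2]:
            idx = rng.choice(arr.shape[2], size=min(n_latent, arr.shape[2]),
                             replace=False)
            for j in sorted(idx):
                scalars[f"{name}[{j}]"] = arr[:, :, j]

    rows = []
    degenerate = []
    for name, arr in scalars.items():
        if np.allclose(arr.var(axis=1), 0.0):
            if np.ptp(arr) == 0.0:
                # identical constant in every chain: a structurally fixed
                # parameter (e.g. sharing scales pinned at 1), not a stuck one
                continue
            degenerate.append(name)
            rows.append((name, np.nan, np.nan))
            continue
        data = az.convert_to_dataset({name: arr})
        rhat = float(az.rhat(data)[name].values)
        ess = float(az.ess(data)[name].values)
        rows.append((name, rhat, ess))
    table = pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])
    finite = table["rhat"].dropna()
    max_rhat = float(finite.max()) if len(finite) else np.nan
    min_ess = float(table["ess"].dropna().min()) if table["ess"].notna().any() else np.nan
    passed = bool(len(finite) and (finite < rhat_threshold).all() and not degenerate)
    return DiagnosticsReport(table, passed, max_rhat, min_ess, degenerate)
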