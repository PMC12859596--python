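import numpy as np
import pytest
from scipy.special import expit, gammaln
from scipy.stats import norm

import hurdlemap as hm
from hurdlemap.gmrf import rw1_precision
from hurdlemap.model import (
    HurdleModel,
    ModelSpec,
    hurdle_loglik,
    linear_predictors,
    log_posterior,
)
from hurdlemap.priors import PCMixingPrior, pc_precision_logpdf
from hurdlemap.synthetic import make_true_params, simulate_covariates


def ztp_logpmf_oracle(k, mu):
    """ZTP pmf by normalising the Poisson pmf over k >= 1."""
    from scipy.stats import poisson

    return poisson.logpmf(k, mu) - np.log1p(-poisson.pmf(0, mu))


@pytest.fixture
def tiny_model():
    graph = hm.make_lattice_graph(3, 3)
    cov = simulate_covariates(graph, 2, 0.3, seed=0)
    rng = np.random.default_rng(1)
    e = rng.uniform(0.5, 2.0, size=(9, 4))
    y = rng.poisson(e)
    return graph, cov, e, y


class TestLinearPredictors:
    def test_null_state_reduces_to_intercepts(self, tiny_model):
        graph, cov, e, y = tiny_model
        params = make_true_params(graph, 4, beta_p=np.zeros(2), alpha_p=0.7,
                                  alpha_b=-0.3, sd_spatial=0, sd_gamma=0,
                                  sd_t=0, sd_st=0)
        eta_b, eta_p = linear_predictors(params, cov, np.ones_like(e))
        assert np.allclose(np.exp(eta_p), np.exp(0.7))
        assert np.allclose(expit(eta_b), expit(-0.3))

    def test_offset_enters_count_component_only(self, tiny_model):
        graph, cov, e, y = tiny_model
        params = make_true_params(graph, 4, beta_p=np.array([0.2, -0.1]), seed=2)
        eta_b1, eta_p1 = linear_predictors(params, cov, e)
        eta_b2, eta_p2 = linear_predictors(params, cov, 2.0 * e)
        assert np.allclose(eta_p2 - eta_p1, np.log(2.0))
        assert np.allclose(eta_b2, eta_b1)

    def test_zero_sharing_decouples_gate(self, tiny_model):
        graph, cov, e, y = tiny_model
        params = make_true_params(graph, 4, beta_p=np.array([0.2, -0.1]),
                                  deltas=(0.0, 0.0, 0.0), seed=3)
        eta_b, _ = linear_predictors(params, cov, e)
        direct = params.alpha_b + (cov.values @ params.beta_b)[:, None]
        assert np.allclose(eta_b, np.broadcast_to(direct, eta_b.shape))

    def test_nonpositive_offset_rejected(self, tiny_model):
        graph, cov, e, y = tiny_model
        params = make_true_params(graph, 4, beta_p=np.zeros(2), seed=4)
        bad = e.copy()
        bad[0, 0] = 0.0
        with pytest.raises(ValueError):
            linear_predictors(params, cov, bad)


class TestHurdleLoglik:
    def test_zero_cell_is_gate_term_only(self):
        assert hurdle_loglik(np.array([0]), np.array([0.25]), np.array([1.0])) \
            == pytest.approx(np.log(0.75))

    def test_positive_cell_matches_ztp_oracle(self):
        val = hurdle_loglik(np.array([1]), np.array([0.5]), np.array([1.0]))
        assert val == pytest.approx(np.log(0.5) + ztp_logpmf_oracle(1, 1.0), rel=1e-10)
        assert val == pytest.approx(-1.234472, abs=1e-6)

    @pytest.mark.parametrize("mu", [0.1, 1.0, 3.0, 10.0])
    def test_count_component_normalises(self, mu):
        # brute-force sum of the ZTP pmf over k = 1..200 equals 1
        ks = np.arange(1, 201)
        log_pmf = (
            ks * np.log(mu) - mu - gammaln(ks + 1.0) - np.log(-np.expm1(-mu))
        )
        assert np.exp(log_pmf).sum() == pytest.approx(1.0, abs=1e-10)

    def test_hurdle_nests_poisson(self):
        # with pi = 1 - e^-mu the hurdle likelihood is the Poisson likelihood
        rng = np.random.default_rng(0)
        mu = rng.uniform(0.05, 5.0, 1000)
        y = rng.poisson(mu)
        pi = -np.expm1(-mu)
        from scipy.stats import poisson

        assert hurdle_loglik(y, pi, mu) == pytest.approx(
            poisson.logpmf(y, mu).sum(), abs=1e-9
        )

    def test_likelihood_increases_as_mu_approaches_y(self):
        # 1-d grid oracle on a single positive cell
        y = np.array([5])
        grid = np.linspace(0.5, 4.5, 30)
        vals = [hurdle_loglik(y, np.array([0.5]), np.array([m])) for m in grid]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hurdle_loglik(np.array([-1]), np.array([0.5]), np.array([1.0]))
        with pytest.raises(ValueError):
            hurdle_loglik(np.array([1.5]), np.array([0.5]), np.array([1.0]))
        with pytest.raises(ValueError):
            hurdle_loglik(np.array([1]), np.array([1.0]), np.array([1.0]))


class TestLogPosterior:
    def test_decomposes_into_likelihood_plus_prior_ordinates(self, tiny_model):
        # spatial off so that every prior term has an independent closed form
        graph, cov, e, y = tiny_model
        spec = ModelSpec(include_spatial=False, share_scales_free=True)
        model = HurdleModel(y, e, cov, graph, spec)
        p = model.zero_params()
        p.alpha_p, p.alpha_b = 0.3, -0.2
        p.beta_p = np.array([0.1, 0.0])
        p.beta_b = np.array([0.0, -0.05])
        lam = -np.log(spec.pc_alpha) / spec.pc_u
        tau_med = (np.log(2) / lam) ** -2  # PC-prior median precision
        p.tau_gamma = p.tau_t = p.tau_st = tau_med
        p.delta_s, p.delta_t, p.delta_st = 1.0, 0.8, 1.2

        eta_b, eta_p = linear_predictors(p, cov, e)
        lik = hurdle_loglik(y, expit(eta_b), np.exp(eta_p))

        # independent per-term density oracle
        prior = norm.logpdf([0.3, -0.2], scale=10).sum()
        prior += norm.logpdf(p.beta_p, scale=10).sum()
        prior += norm.logpdf(p.beta_b, scale=10).sum()
        rw = rw1_precision(4)
        lam_e, vec = np.linalg.eigh(rw.Q.toarray() * rw.scaling)
        keep = lam_e > 1e-9
        prior += 0.5 * np.log(lam_e[keep]).sum() - 0.5 * keep.sum() * np.log(2 * np.pi)
        prior += norm.logpdf(p.z_t).sum()
        prior += norm.logpdf(p.z_st).sum()
        prior += 3 * float(pc_precision_logpdf(tau_med, spec.pc_u, spec.pc_alpha))
        for d in (1.0, 0.8, 1.2):
            prior += norm.logpdf(np.log(d)) - np.log(d)

        assert model.log_posterior(p) == pytest.approx(lik + prior, rel=1e-10)

    def test_invariant_to_recentred_level_shift_in_gamma(self, tiny_model):
        graph, cov, e, y = tiny_model
        model = HurdleModel(y, e, cov, graph)
        p = model.init_params(np.random.default_rng(5))
        before = model.log_posterior(p)
        p.w = p.w + 1.7
        p.w -= p.w.mean()  # project back to the constraint
        assert model.log_posterior(p) == pytest.approx(before, rel=1e-12)

    def test_constraint_violation_rejected(self, tiny_model):
        graph, cov, e, y = tiny_model
        model = HurdleModel(y, e, cov, graph)
        p = model.init_params(np.random.default_rng(6))
        p.u = p.u + 1.0  # break per-component sum-to-zero
        with pytest.raises(ValueError):
            model.log_posterior(p)

    def test_permutation_equivariance(self):
        # relabelling areas consistently everywhere leaves the density unchanged
        graph = hm.make_lattice_graph(3, 3)
        cov = simulate_covariates(graph, 2, 0.4, seed=7)
        rng = np.random.default_rng(8)
        e = rng.uniform(0.5, 2.0, size=(9, 3))
        y = rng.poisson(e)
        spec = ModelSpec()
        model = HurdleModel(y, e, cov, graph, spec)
        p = model.init_params(np.random.default_rng(9))
        base = model.log_posterior(p)

        perm = rng.permutation(9)
        inv = np.argsort(perm)
        pedges = inv[graph.edges]
        pgraph = hm.AreaGraph(9, pedges)
        pcov = hm.CovariateMatrix(cov.values[perm], cov.names)
        pmodel = HurdleModel(y[perm], e[perm], pcov, pgraph, spec)
        pp = p.copy()
        pp.u, pp.v, pp.z_st = p.u[perm], p.v[perm], p.z_st[perm]
        assert pmodel.log_posterior(pp) == pytest.approx(base, rel=1e-9)


class TestPriors:
    def test_pc_precision_density_normalises(self):
        from scipy.integrate import quad

        total, _ = quad(
            lambda t: np.exp(pc_precision_logpdf(t, 1.0, 0.01)), 1e-9, np.inf
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_pc_precision_tail_statement(self):
        # P(1/sqrt(tau) > u) = alpha <=> P(tau < u^-2) = alpha
        from scipy.integrate import quad

        u, alpha = 1.0, 0.01
        below, _ = quad(
            lambda t: np.exp(pc_precision_logpdf(t, u, alpha)), 1e-12, u**-2.0
        )
        assert below == pytest.approx(alpha, abs=1e-6)

    def test_mixing_prior_is_proper_and_honours_statement(self):
        from hurdlemap.gmrf import icar_precision

        s = icar_precision(hm.make_lattice_graph(5, 5))
        cov_eigs = 1.0 / (s.scaling * s.positive_eigvals)
        prior = PCMixingPrior(cov_eigs, u=0.5, alpha=0.5)
        grid = prior.grid
        pdf = np.exp(prior.logpdf(grid))
        assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=1e-3)
        if prior.attainable:
            assert prior.cdf(0.5) == pytest.approx(0.5, abs=5e-3)
        draws = prior.sample(np.random.default_rng(0), 20000)
        assert abs((draws < 0.5).mean() - prior.cdf(0.5)) < 0.02

    def test_log_posterior_wrapper_matches_model(self, tiny_model):
        graph, cov, e, y = tiny_model
        spec = ModelSpec()
        model = HurdleModel(y, e, cov, graph, spec)
        p = model.init_params(np.random.default_rng(10))
        assert log_posterior(p, spec, y, e, cov, graph) == pytest.approx(
            model.log_posterior(p)
        )
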