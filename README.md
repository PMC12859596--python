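# hurdlemap

Bayesian spatio-temporal small-area disease mapping for **rare events**:
a hurdle Poisson model with shared spatial, temporal and space-time
random effects, indirect age-sex standardisation, MCMC inference, and
the posterior summaries epidemiologists actually report — relative
risks with credible intervals, exceedance-probability evidence bands,
percent risk change per standard deviation of each covariate, variance
decomposition, and covariate profiles across risk percentiles.

It is aimed at analyses such as annual suicide counts across thousands
of census areas of 5,000–15,000 residents, where most area-years record
zero events and naive Poisson regression mishandles the excess zeros.
Because such mortality data are usually access-restricted, the package
ships a synthetic-data module that generates whole studies (geography,
stratified populations, spatially correlated covariates, counts) from
the model itself, with known ground truth.

## Model

For area $i$ with covariates $x_i$ and year $t$, the observed count
$y_{it}$ with indirectly standardised expected count $E_{it}$ follows a
two-part (hurdle) law

$$
P(y_{it}=0)=1-\pi_{it},\qquad
P(y_{it}=k)=\pi_{it}\,\frac{\mu_{it}^k e^{-\mu_{it}}}{k!\,(1-e^{-\mu_{it}})},\quad k\ge 1,
$$

a Bernoulli gate and a zero-truncated Poisson, with linear predictors

$$
\log \mu_{it} = \log E_{it} + \alpha_p + x_i^\top\beta_p + b_i + \gamma_t + \phi_t + \psi_{it},
$$
$$
\operatorname{logit} \pi_{it} = \alpha_b + x_i^\top\beta_b
 + \delta_s b_i + \delta_t(\gamma_t + \phi_t) + \delta_{st}\psi_{it}.
$$

Here $b_i$ is a BYM2 spatial effect (scaled intrinsic CAR mixed with an
unstructured term via mixing parameter $\phi$), $\gamma_t$ a
first-order random walk, $\phi_t$ an exchangeable temporal effect and
$\psi_{it}$ an exchangeable space-time interaction. The gate borrows
the count component's random effects through scalar sharing
coefficients $\delta$. Precisions and the mixing parameter carry
penalised-complexity priors; intercepts, coefficients and log sharing
scales carry Gaussian priors. Inference is by a blocked adaptive
Metropolis-within-Gibbs sampler with split-$\hat R$/ESS diagnostics
(see `docs/methods.md`).

## Worked example

```python
import numpy as np
import hurdlemap as hm

graph = hm.make_lattice_graph(8, 8)
covariates = hm.simulate_covariates(graph, K=3, spatial_corr=0.5, seed=1)
truth = hm.make_true_params(graph, n_years=8,
                            beta_p=np.array([0.18, -0.08, 0.0]), seed=2)
panel, ground_truth = hm.simulate_dataset(graph, covariates, truth,
                                          n_years=8, seed=3)
expected = hm.compute_expected_counts(panel, hm.compute_reference_rates(panel))
spec = hm.ModelSpec(share_scales_free=False)  # sharing coefficients pinned at 1
samples = hm.run_mcmc(panel.totals(), expected, covariates, graph, spec,
                      n_chains=2, n_iter=8000, n_warmup=3000, thin=2, seed=4)
print(hm.convergence_diagnostics(samples))
beta = samples.get("beta_p", combined=True)
for j, name in enumerate(covariates.names):
    s = hm.percent_change_per_sd(beta[:, j])
    print(f"{name}: {s['median']:+.2f}% per SD "
          f"(95% CrI {s['ci_low']:+.2f}%, {s['ci_high']:+.2f}%)")
print(hm.relative_risk(samples, covariates, "area",
                       area_ids=panel.area_ids).head(3).to_string(index=False))
```

prints (about 40 s on one CPU):

```
DiagnosticsReport(passed=True, max_rhat=1.0233, min_ess=98.1, degenerate=[])
cov1: +20.24% per SD (95% CrI +2.90%, +41.33%)
cov2: -1.33% per SD (95% CrI -16.18%, +15.75%)
cov3: +1.23% per SD (95% CrI -13.39%, +17.90%)
     area   median   ci_low  ci_high  exceedance category
area_0000 0.888130 0.489932 1.670741      0.3486   medium
area_0001 0.551081 0.273691 0.992565      0.0240      low
area_0002 0.676459 0.349821 1.162157      0.0870      low
```

The study was generated with a true +19.7% per-SD effect of the first
covariate (`beta = 0.18`) and null/negative effects for the others; the
fitted percent changes recover this within their credible intervals.
The relative-risk table reads as usual for disease mapping: area 1 has
roughly half the national average risk, with exceedance probability
0.02 — "low" evidence of excess risk (bands: low [0, 0.2], medium
(0.2, 0.8], high (0.8, 1]). Estimating the sharing coefficients
(`share_scales_free=True`, the default) is also supported; it makes the
gate's own covariate coefficients weakly identified when covariates are
spatially smooth, and correspondingly slower to mix — see
`docs/methods.md`.

A one-command version of the same workflow exists on the shell:

```bash
hurdlemap simulate --out data --rows 10 --cols 10 --years 10 --seed 1
hurdlemap standardise --counts data/counts.csv --graph data/graph.txt \
    --covariates data/covariates.csv --out data/expected.csv
hurdlemap run --config run.cfg        # full pipeline from a key=value config
```

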