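import numpy as np
import pandas as pd
import pytest

import hurdlemap as hm
from hurdlemap.inference import run_mcmc


@pytest.fixture(scope="session")
def toy_panel() -> hm.StratifiedPanel:
    """Two areas, one year, two strata (young/old), single sex label.

    populations: area1 = (100, 200), area2 = (300, 400)
    deaths:      area1 = (1, 4),     area2 = (2, 3)
    """
    rows = [
        ("a1", 2000, "young", "all", 100, 1),
        ("a1", 2000, "old", "all", 200, 4),
        ("a2", 2000, "young", "all", 300, 2),
        ("a2", 2000, "old", "all", 400, 3),
    ]
    df = pd.DataFrame(
        rows, columns=["area_id", "year", "age_band", "sex", "population", "deaths"]
    )
    return hm.StratifiedPanel(df, age_bands=["young", "old"], sexes=["all"])


@pytest.fixture(scope="session")
def small_study():
    """A 6x6-lattice synthetic study with known truth, used by several tests."""
    graph = hm.make_lattice_graph(6, 6)
    cov = hm.simulate_covariates(graph, 3, 0.4, seed=11)
    params = hm.make_true_params(
        graph, 5, beta_p=np.array([0.2, -0.1, 0.0]), seed=12
    )
    panel, truth = hm.simulate_dataset(graph, cov, params, n_years=5, seed=13)
    expected = hm.compute_expected_counts(panel, hm.compute_reference_rates(panel))
    return {
        "graph": graph,
        "cov": cov,
        "params": params,
        "panel": panel,
        "truth": truth,
        "expected": expected,
    }


@pytest.fixture(scope="session")
def small_fit(small_study):
    """A short but usable posterior fit of the small synthetic study."""
    s = small_study
    return run_mcmc(
        s["panel"].totals(), s["expected"], s["cov"], s["graph"],
        n_chains=2, n_iter=700, n_warmup=350, seed=21,
    )


def make_samples(**arrays) -> hm.PosteriorSamples:
    """Hand-construct a PosteriorSamples from (chain, draw, ...) arrays."""
    return hm.PosteriorSamples({k: np.asarray(v, dtype=float) for k, v in arrays.items()})
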