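import numpy as np
import pandas as pd
import pytest

import hurdlemap as hm
from hurdlemap.summaries import (
    classify_exceedance,
    percent_change_per_sd,
    profile_table,
    relative_risk,
    rr_contrast,
    rr_draws,
    variance_decomposition,
)

from conftest import make_samples


def _samples(n=3, t=2, d=2, **over):
    """Fake posterior with all latent terms zero unless overridden."""
    base = dict(
        beta_p=np.zeros((1, d, 1)),
        b=np.zeros((1, d, n)),
        gamma=np.zeros((1, d, t)),
        phi_t=np.zeros((1, d, t)),
        psi=np.zeros((1, d, n, t)),
    )
    base.update(over)
    return make_samples(**base)


class TestRelativeRisk:
    def test_null_draws_give_unit_rr_everywhere(self):
        s = _samples()
        x = np.zeros((3, 1))
        for level in ("year", "area", "area-year"):
            tab = relative_risk(s, x, level)
            assert np.allclose(tab["median"], 1.0)
            assert np.allclose(tab["ci_low"], 1.0)
            assert np.allclose(tab["ci_high"], 1.0)
            # RR exactly 1 does not exceed 1 (strict comparison)
            assert np.allclose(tab["exceedance"], 0.0)

    def test_constant_spatial_effect_is_exact(self):
        b = np.full((1, 2, 3), 0.0)
        b[:, :, 1] = np.log(2.0)
        tab = relative_risk(_samples(b=b), np.zeros((3, 1)), "area")
        assert tab.loc[1, "median"] == pytest.approx(2.0)
        assert tab.loc[1, "exceedance"] == 1.0

    def test_hand_enumerated_two_draw_oracle(self):
        # 3 areas, 2 draws with hand-set spatial effects and coefficients
        x = np.array([[1.0], [0.0], [-1.0]])
        beta = np.array([[[0.1], [0.3]]])  # (1, 2, 1)
        b = np.array([[[0.2, 0.0, -0.2], [0.4, 0.0, -0.4]]])  # (1, 2, 3)
        s = _samples(beta_p=beta, b=b)
        tab = relative_risk(s, x, "area")
        draws = np.exp(np.array([
            [0.1 * 1 + 0.2, 0.0, 0.1 * -1 - 0.2],
            [0.3 * 1 + 0.4, 0.0, 0.3 * -1 - 0.4],
        ]))
        for i in range(3):
            lo, med, hi = np.quantile(draws[:, i], [0.025, 0.5, 0.975])
            assert tab.loc[i, "median"] == pytest.approx(med)
            assert tab.loc[i, "ci_low"] == pytest.approx(lo)
            assert tab.loc[i, "ci_high"] == pytest.approx(hi)
            assert tab.loc[i, "exceedance"] == (draws[:, i] > 1).mean()

    def test_region_year_is_expected_count_weighted_mean(self):
        b = np.array([[[np.log(2.0), np.log(4.0)]]])  # 1 draw, 2 areas
        s = _samples(n=2, t=1, d=1, b=b)
        x = np.zeros((2, 1))
        region_map = np.array(["r1", "r1"])
        weights = np.array([[1.0], [3.0]])
        draws = rr_draws(s, x, "region-year", region_map, weights)
        assert draws[0, 0, 0] == pytest.approx((1 * 2 + 3 * 4) / 4)

    def test_region_level_requires_map_and_weights(self):
        with pytest.raises(ValueError, match="region"):
            rr_draws(_samples(), np.zeros((3, 1)), "region-year")

    def test_exceedance_complement_sums_to_one(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0, 0.3, size=(1, 50, 3))
        b[:, :10, 0] = 0.0  # point mass at RR = 1 for one unit
        draws = rr_draws(_samples(d=50, b=b), np.zeros((3, 1)), "area")
        above = (draws > 1).mean(axis=0)
        below = (draws < 1).mean(axis=0)
        at = (draws == 1).mean(axis=0)
        assert np.allclose(above + below + at, 1.0)


class TestContrast:
    def test_identical_units_give_zero(self):
        out = rr_contrast(_samples(), np.zeros((3, 1)), "area", 1, 1)
        assert out == {"median": 0.0, "ci_low": 0.0, "ci_high": 0.0}

    def test_doubled_risk_gives_hundred_percent(self):
        b = np.zeros((1, 2, 3))
        b[:, :, 0] = np.log(2.0)
        out = rr_contrast(_samples(b=b), np.zeros((3, 1)), "area", 0, 1)
        assert out["median"] == pytest.approx(100.0)

    def test_two_draw_enumeration_oracle(self):
        b = np.array([[[0.1, -0.1, 0.0], [0.5, 0.2, 0.0]]])
        out = rr_contrast(_samples(b=b), np.zeros((3, 1)), "area", 0, 1)
        pct = 100 * (np.exp([0.1 - -0.1, 0.5 - 0.2]) - 1)
        assert out["median"] == pytest.approx(np.quantile(pct, 0.5))
        assert out["ci_low"] == pytest.approx(np.quantile(pct, 0.025))

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            rr_contrast(_samples(), np.zeros((3, 1)), "area", 0, 7)


class TestClassifyExceedance:
    @pytest.mark.parametrize(
        "p,label",
        [(0.0, "low"), (0.2, "low"), (0.200001, "medium"), (0.5, "medium"),
         (0.8, "medium"), (0.801, "high"), (1.0, "high")],
    )
    def test_band_boundaries(self, p, label):
        assert classify_exceedance(p) == label

    def test_outside_unit_interval_rejected(self):
        for p in (-0.01, 1.01):
            with pytest.raises(ValueError):
                classify_exceedance(p)

    def test_monotone_step_function(self):
        grid = np.linspace(0, 1, 401)
        order = {"low": 0, "medium": 1, "high": 2}
        codes = [order[classify_exceedance(p)] for p in grid]
        assert np.all(np.diff(codes) >= 0)


class TestPercentChange:
    def test_zero_coefficient(self):
        out = percent_change_per_sd(np.zeros(10))
        assert out["median"] == 0.0

    def test_log_two_gives_hundred_percent(self):
        out = percent_change_per_sd(np.full(10, np.log(2.0)))
        assert out["median"] == pytest.approx(100.0)

    def test_two_draw_quantile_rule(self):
        # quantiles on the coefficient scale, then transformed
        draws = np.array([0.0, np.log(1.5)])
        out = percent_change_per_sd(draws)
        assert out["median"] == pytest.approx(
            100 * np.expm1(np.quantile(draws, 0.5)))
        assert out["median"] == pytest.approx(22.474, abs=1e-2)
        assert out["ci_low"] == pytest.approx(
            100 * np.expm1(np.quantile(draws, 0.025)))

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            percent_change_per_sd(np.array([]))


class TestVarianceDecomposition:
    def test_covariate_only_draws(self):
        x = np.array([[1.0], [0.0], [-1.0]])
        beta = np.array([[[0.5], [0.7]]])
        tab = variance_decomposition(_samples(beta_p=beta), x).set_index("component")
        assert tab.loc["covariates", "median"] == pytest.approx(100.0)
        for comp in ("spatial", "temporal", "spatio-temporal"):
            assert tab.loc[comp, "median"] == 0.0

    def test_equal_independent_components_split_evenly(self):
        # spatial and covariate fields constructed orthogonal with equal
        # variance: direct-variance oracle gives 50/50
        x = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        beta = np.ones((1, 1, 1))
        b = np.array([[[1.0, 1.0, -1.0, -1.0]]])
        tab = variance_decomposition(
            _samples(n=4, d=1, beta_p=beta, b=b), x
        ).set_index("component")
        assert tab.loc["covariates", "median"] == pytest.approx(50.0)
        assert tab.loc["spatial", "median"] == pytest.approx(50.0)

    def test_negatively_covarying_components_sum_over_hundred(self):
        x = np.array([[1.0], [0.0], [-1.0]])
        beta = np.ones((1, 1, 1))
        b = np.array([[[-0.5, 0.0, 0.5]]])  # anti-correlated with x' beta
        tab = variance_decomposition(
            _samples(d=1, beta_p=beta, b=b), x
        ).set_index("component")
        assert tab["median"].sum() > 100.0

    def test_all_zero_draws_rejected(self):
        with pytest.raises(ValueError):
            variance_decomposition(_samples(), np.zeros((3, 1)))


class TestProfileTable:
    def _rr_frame(self, medians, areas=None, years=None):
        n = len(medians)
        return pd.DataFrame({
            "area": areas if areas is not None else np.arange(n),
            "year": years if years is not None else np.zeros(n, int),
            "median": medians,
        })

    def test_rank_consistent_covariate_increases_across_bins(self):
        # single year so that the unit's covariate equals log median RR
        rng = np.random.default_rng(0)
        log_rr = rng.normal(0, 1, 300)
        cov = hm.CovariateMatrix(log_rr[:, None], ["score"])
        tab = profile_table(self._rr_frame(np.exp(log_rr)), cov)
        assert np.all(np.diff(tab["score"]) > 0)

    def test_constant_covariate_gives_zero_means(self):
        cov = hm.CovariateMatrix(np.zeros((150, 1)), ["flat"])
        tab = profile_table(self._rr_frame(np.linspace(0.5, 2, 150)), cov)
        assert np.allclose(tab["flat"], 0.0)

    def test_two_hundred_units_give_bins_of_two(self):
        # 100 areas x 2 years
        medians = np.linspace(0.5, 2.0, 200)
        frame = self._rr_frame(
            medians,
            areas=np.repeat(np.arange(100), 2),
            years=np.tile([0, 1], 100),
        )
        cov = hm.CovariateMatrix(np.random.default_rng(1).normal(size=(100, 1)), ["c"])
        tab = profile_table(frame, cov)
        assert len(tab) == 100
        # partition: every unit in exactly one bin of size 2
        sizes = [len(c) for c in np.array_split(np.arange(200), 100)]
        assert sizes == [2] * 100

    def test_fewer_units_than_bins_reduces_bin_count(self):
        cov = hm.CovariateMatrix(np.zeros((30, 1)), ["c"])
        tab = profile_table(self._rr_frame(np.linspace(1, 2, 30)), cov)
        assert len(tab) == 30

    def test_bin_sizes_differ_by_at_most_one(self):
        cov = hm.CovariateMatrix(np.zeros((157, 1)), ["c"])
        tab = profile_table(self._rr_frame(np.linspace(1, 2, 157)), cov)
        sizes = [len(c) for c in np.array_split(np.arange(157), 100)]
        assert max(sizes) - min(sizes) <= 1
        assert len(tab) == 100


def test_year_rr_centred_on_real_fit(small_fit):
    # sum-to-zero temporal constraints centre the year-level log RR series
    draws = small_fit.get("gamma", combined=True) + small_fit.get("phi_t", combined=True)
    mean_log = draws.mean(axis=1)  # per-draw mean over years
    se = mean_log.std()
    assert abs(mean_log.mean()) < 3 * max(se, 1e-6)
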