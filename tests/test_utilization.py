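import warnings

import numpy as np
import pandas as pd
import pytest

from gorillaspace import (
    autocorrelation_term,
    build_utilization_table,
    distance_per_cell_table,
    fit_utilization_model,
    likelihood_ratio_full_null,
    simulate_utilization_rows,
    within_between,
)
from gorillaspace.lmm import fit_lmm
from gorillaspace.previous_use import UsageLedger


class TestWithinBetween:
    def test_single_group(self):
        w, b = within_between([1.0, 2.0, 3.0], ["g"] * 3)
        np.testing.assert_allclose(w, [-1, 0, 1])
        np.testing.assert_allclose(b, [2, 2, 2])

    def test_two_groups_between_is_group_mean(self):
        x = [1.0, 3.0, 8.0, 12.0]
        w, b = within_between(x, ["a", "a", "b", "b"])
        np.testing.assert_allclose(b, [2, 2, 10, 10])

    def test_reconstruction_and_zero_within_means(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        g = rng.integers(0, 7, 200)
        w, b = within_between(x, g)
        np.testing.assert_allclose(w + b, x, atol=1e-12)
        for gg in np.unique(g):
            assert abs(w[g == gg].mean()) < 1e-12


class TestAutocorrelationTerm:
    def _rows(self, n=30, groups=3, seed=1):
        rng = np.random.default_rng(seed)
        return (rng.integers(0, groups, n),             # group
                rng.integers(0, 100, n).astype(float),  # day
                rng.uniform(0, 5000, n),                # cx
                rng.uniform(0, 5000, n),                # cy
                rng.normal(size=n))                     # residuals

    def test_zero_residuals_give_zero_terms(self):
        g, d, x, y, _ = self._rows()
        term = autocorrelation_term(g, d, x, y, np.zeros(len(g)), 7, 500)
        np.testing.assert_allclose(term, 0.0)

    def test_infinite_scales_give_unweighted_mean_of_others(self):
        g, d, x, y, r = self._rows()
        term = autocorrelation_term(g, d, x, y, r, 1e12, 1e12)
        for i in range(len(g)):
            others = r[(g == g[i]) & (np.arange(len(g)) != i)]
            assert term[i] == pytest.approx(others.mean(), abs=1e-9)

    def test_singleton_group_gets_zero(self):
        g = np.array([0, 1, 1])
        term = autocorrelation_term(g, [0.0, 1.0, 2.0], [0, 0, 0], [0, 0, 0],
                                    [5.0, 1.0, 3.0], 7, 500)
        assert term[0] == 0.0

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation_term([0], [0.0], [0.0], [0.0], [1.0], 0, 500)


class TestMixedModelEngine:
    def test_matches_statsmodels_single_random_effect(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(5)
        n = 200
        g = rng.integers(0, 8, n)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 0.5, -0.2] + rng.normal(0, 0.4, 8)[g] \
            + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x1": X[:, 1], "x2": X[:, 2], "g": g})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = smf.mixedlm("y ~ x1 + x2", df, groups="g").fit(reml=False)
        mine = fit_lmm(y, X, {"g": g})
        assert mine.log_likelihood == pytest.approx(ref.llf, abs=1e-4)
        np.testing.assert_allclose(mine.beta, ref.fe_params.values, atol=1e-5)
        assert mine.variance_components["g"] == pytest.approx(
            ref.cov_re.values[0, 0], abs=1e-3)

    def test_zero_variance_reduces_to_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [0.5, 1.0] + rng.normal(0, 1, n)   # no group structure at all
        g = rng.integers(0, 5, n)
        mine = fit_lmm(y, X, {"g": g})
        ols = sm.OLS(y, X).fit()
        # the variance component collapses to (near) zero and the fit is OLS
        assert mine.variance_components["g"] < 0.05
        assert mine.log_likelihood == pytest.approx(ols.llf, abs=0.05)
        np.testing.assert_allclose(mine.beta, ols.params, atol=0.02)

    def test_variance_components_nonnegative(self):
        rows = simulate_utilization_rows(n_rows_total=200, seed=7)
        fit = fit_utilization_model(rows, starts=(0.1,))
        assert all(v >= 0 for v in fit.variance_components.values())
        assert fit.sigma2 > 0


class TestUtilizationFitAndLRT:
    def test_full_ll_at_least_null_ll(self):
        rows = simulate_utilization_rows(n_rows_total=250, seed=8)
        full = fit_utilization_model(rows, starts=(0.1,))
        null = fit_utilization_model(rows, include_predictors=False,
                                     starts=(0.1,))
        assert full.log_likelihood >= null.log_likelihood - 1e-6
        stat, df, p = likelihood_ratio_full_null(full, null)
        assert stat >= 0 and df == 6 and 0 <= p <= 1

    def test_negative_between_neighbour_effect_recovered(self):
        # -0.5 sd on a group-level predictor: with 10 groups this is the
        # regime where the sign is reliably determined (|effect|/SE ~ 3)
        neg = 0
        for r in range(10):
            rows = simulate_utilization_rows(
                n_rows_total=400, seed=900 + r,
                betas={"prev_nbr_between": -0.5})
            fit = fit_utilization_model(rows, starts=(0.1,))
            neg += fit.coefficient("prev_nbr_between") < 0
        assert neg >= 9

    def test_strong_effects_yield_small_lrt_p(self):
        rows = simulate_utilization_rows(
            n_rows_total=400, seed=10,
            betas={"food_within": 0.5, "prev_self_within": 0.4,
                   "prev_nbr_between": -0.5})
        full = fit_utilization_model(rows, starts=(0.1,))
        null = fit_utilization_model(rows, include_predictors=False,
                                     starts=(0.1,))
        _, _, p = likelihood_ratio_full_null(full, null)
        assert p < 0.01


def test_build_utilization_table_from_tracks(small_sim):
    grid = small_sim.config.grid
    visits = distance_per_cell_table(small_sim.fixes, grid)
    ledger = UsageLedger.from_cell_visits(visits, small_sim.group_sizes)
    rows = build_utilization_table(visits, small_sim.energy_field, ledger,
                                   grid)
    # zero-distance visits dropped, response is log distance
    assert np.isfinite(rows["response"]).all()
    np.testing.assert_allclose(rows["response"],
                               np.log(rows["distance_m"]))
    # within-group parts average to ~0 per group
    for p in ("food", "prev_self", "prev_nbr"):
        means = rows.groupby("group")[p + "_within"].mean()
        np.testing.assert_allclose(means, 0.0, atol=1e-10)
    # decomposition reconstructs the transformed predictor
    z, _ = (rows["food_within"] + rows["food_between"]), None
    state = rows.attrs["transform_states"]["food"]
    np.testing.assert_allclose(z, state.apply(rows["food"]), atol=1e-10)
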