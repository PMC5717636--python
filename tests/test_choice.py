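
import numpy as np
import pandas as pd
import pytest

from gorillaspace import (
    TransformState,
    UsageLedger,
    build_choice_table,
    extract_entry_decisions_table,
    fit_choice_model,
    log_z_transform,
    permutation_full_null,
    simulate_choice_sets,
)
from gorillaspace.choice import null_log_likelihood
from gorillaspace.tracks import EntryDecision


class TestLogZTransform:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        y, state = log_z_transform(rng.gamma(2, 3, 500))
        assert abs(y.mean()) < 1e-12
        assert y.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_monotone(self):
        x = np.array([0.0, 0.5, 1.0, 10.0, 100.0])
        y, _ = log_z_transform(x)
        assert (np.diff(y) > 0).all()

    def test_zero_maps_finite_via_half_min_shift(self):
        x = np.array([0.0, 4.0, 9.0])
        y, state = log_z_transform(x)
        assert np.isfinite(y).all()
        assert state.shift == pytest.approx(2.0)  # half the min positive

    def test_all_zero_uses_unit_shift_but_errors_on_variance(self):
        with pytest.raises(ValueError, match="variance"):
            log_z_transform(np.zeros(5))

    def test_state_replay_on_new_data(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        _, state = log_z_transform(x)
        y_new, state2 = log_z_transform(np.array([2.0, 5.0]), state)
        assert state2 is state
        np.testing.assert_allclose(
            y_new, (np.log(np.array([2.0, 5.0]) + state.shift)
                    - state.mean) / state.sd)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            log_z_transform(np.array([-1.0, 2.0]))


@pytest.fixture()
def toy_table(grid, patchy_field):
    """Choice table from hand-made decisions on the 4x4 test grid."""
    ledger = UsageLedger(
        pd.DataFrame({"group": ["g1"], "cell_i": [1], "cell_j": [1],
                      "date": [pd.Timestamp("2012-09-20")],
                      "distance_m": [300.0]}),
        pd.DataFrame({"group": ["g1", "g2"], "year": 2012, "month": 10,
                      "size": [8, 12]}))
    decisions = []
    rng = np.random.default_rng(3)
    for k in range(12):
        origin = (int(rng.integers(4)), int(rng.integers(4)))
        cands = tuple(c for c in grid.neighbours(*origin)
                      if not patchy_field.mask[c[0], c[1]])
        chosen = cands[int(rng.integers(len(cands)))]
        decisions.append(EntryDecision(
            "g1", pd.Timestamp("2012-10-01") + pd.Timedelta(days=k),
            origin, chosen, cands))
    return build_choice_table(decisions, patchy_field, ledger)


class TestBuildChoiceTable:
    def test_offset_is_log_inverse_candidate_count(self, toy_table):
        sizes = toy_table.groupby("choice_id")["chosen"].size()
        offsets = toy_table.groupby("choice_id")["offset"].first()
        np.testing.assert_allclose(offsets, -np.log(sizes))

    def test_exactly_one_chosen_per_set(self, toy_table):
        assert (toy_table.groupby("choice_id")["chosen"].sum() == 1).all()

    def test_corner_flag_matches_geometry(self, toy_table):
        di = toy_table["cell_i"] - toy_table["origin_i"]
        dj = toy_table["cell_j"] - toy_table["origin_j"]
        np.testing.assert_array_equal(toy_table["is_corner"],
                                      (di != 0) & (dj != 0))

    def test_transform_states_recorded(self, toy_table):
        states = toy_table.attrs["transform_states"]
        assert set(states) == {"food", "prev_self", "prev_nbr"}


class TestFitChoiceModel:
    def test_null_log_likelihood_exact(self):
        table = simulate_choice_sets(100, seed=0,
                                     candidate_counts=(8,))
        fit = fit_choice_model(
            table, predictors=["food_z", "prev_self_z", "prev_nbr_z"])
        assert fit.null_log_likelihood == pytest.approx(-100 * np.log(8))
        assert null_log_likelihood(table) == pytest.approx(-100 * np.log(8))

    def test_matches_grid_search_oracle_on_two_alternatives(self):
        rng = np.random.default_rng(4)
        rows = []
        beta_true = 0.8
        for s in range(50):
            x = rng.normal(size=2)
            p = np.exp(beta_true * x)
            chosen = rng.choice(2, p=p / p.sum())
            for k in range(2):
                rows.append({"choice_id": s, "x": x[k],
                             "chosen": int(k == chosen), "is_corner": False,
                             "offset": -np.log(2)})
        table = pd.DataFrame(rows)
        fit = fit_choice_model(table, predictors=["x"])
        # brute-force profile of the conditional log-likelihood
        grid_b = np.arange(-3, 3, 1e-3)
        x = table["x"].to_numpy().reshape(-1, 2)
        ch = table["chosen"].to_numpy().reshape(-1, 2).argmax(axis=1)
        eta = grid_b[:, None, None] * x[None, :, :]
        ll = (np.take_along_axis(eta, ch[None, :, None], axis=2)[:, :, 0]
              - np.log(np.exp(eta).sum(axis=2))).sum(axis=1)
        best = grid_b[np.argmax(ll)]
        assert fit.coefficients["x"] == pytest.approx(best, abs=1e-3)

    def test_matches_statsmodels_conditional_logit(self):
        import statsmodels.api as sm
        table = simulate_choice_sets(300, betas=(0.5, 0.3, -0.3), seed=5)
        preds = ["food_z", "prev_self_z", "prev_nbr_z"]
        fit = fit_choice_model(table, predictors=preds)
        ref = sm.ConditionalLogit(
            table["chosen"], table[preds], groups=table["choice_id"]
        ).fit(disp=0)
        np.testing.assert_allclose(
            [fit.coefficients[p] for p in preds], ref.params, atol=1e-3)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-4)
        assert fit.log_likelihood >= ref.llf - 1e-8  # at least as good an optimum

    def test_ll_invariant_to_set_constant_shift(self):
        table = simulate_choice_sets(100, betas=(0.5, 0.0, 0.0), seed=6)
        preds = ["food_z", "prev_self_z", "prev_nbr_z"]
        fit1 = fit_choice_model(table, predictors=preds)
        shifted = table.copy()
        per_set = shifted.groupby("choice_id")["food_z"].transform("size")
        shifted["food_z"] = shifted["food_z"] + per_set * 3.7
        fit2 = fit_choice_model(shifted, predictors=preds)
        assert fit2.log_likelihood == pytest.approx(fit1.log_likelihood,
                                                    abs=1e-6)

    def test_separation_flagged_not_converged(self):
        rows = []
        for s in range(20):
            for k in range(2):
                rows.append({"choice_id": s, "x": float(k),
                             "chosen": int(k == 1), "is_corner": False,
                             "offset": -np.log(2)})
        fit = fit_choice_model(pd.DataFrame(rows), predictors=["x"])
        assert not fit.converged

    def test_two_chosen_rows_rejected(self):
        table = simulate_choice_sets(5, seed=7)
        table.loc[1, "chosen"] = 1
        with pytest.raises(ValueError):
            fit_choice_model(table,
                             predictors=["food_z", "prev_self_z", "prev_nbr_z"])


class TestPermutationFullNull:
    PREDS = ["food_z", "prev_self_z", "prev_nbr_z"]

    def test_observed_stat_nonnegative_and_deterministic(self):
        table = simulate_choice_sets(80, betas=(0.4, 0, 0), seed=8)
        r1 = permutation_full_null(table, n_perm=50, seed=1,
                                   predictors=self.PREDS)
        r2 = permutation_full_null(table, n_perm=50, seed=1,
                                   predictors=self.PREDS)
        assert r1.observed_stat >= 0
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_stats, r2.null_stats)

    def test_p_value_follows_add_one_rule(self):
        table = simulate_choice_sets(80, betas=(0.8, 0, 0), seed=9)
        r = permutation_full_null(table, n_perm=99, seed=2,
                                  predictors=self.PREDS)
        expected = (1 + np.sum(r.null_stats >= r.observed_stat)) / 100
        assert r.p_value == pytest.approx(expected)
        assert 0 < r.p_value <= 1

    def test_strong_effect_detected(self):
        table = simulate_choice_sets(400, betas=(1.0, 0.5, 0), seed=10)
        r = permutation_full_null(table, n_perm=99, seed=3,
                                  predictors=self.PREDS)
        assert r.p_value == pytest.approx(1 / 100)

    def test_invalid_n_perm(self):
        table = simulate_choice_sets(10, seed=11)
        with pytest.raises(ValueError):
            permutation_full_null(table, n_perm=0, seed=0,
                                  predictors=self.PREDS)


def test_choice_table_from_simulated_tracks(small_sim):
    """End-to-end: simulator fixes -> decisions -> choice table invariants."""
    from gorillaspace import distance_per_cell_table
    grid = small_sim.config.grid
    visits = distance_per_cell_table(small_sim.fixes, grid)
    ledger = UsageLedger.from_cell_visits(visits, small_sim.group_sizes)
    decisions = extract_entry_decisions_table(
        small_sim.fixes, grid, small_sim.energy_field)
    table = build_choice_table(decisions, small_sim.energy_field, ledger,
                               transform_states=small_sim.transform_states)
    assert (table.groupby("choice_id")["chosen"].sum() == 1).all()
    counts = table.groupby("choice_id")["chosen"].size()
    assert counts.between(2, 8).all()
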