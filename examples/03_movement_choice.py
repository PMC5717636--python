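"""Movement-choice model on simulated multi-group tracking data.

Simulates ten groups whose daily cell choices respond to food (+), their own
previous use (+, site fidelity) and neighbours' previous use (-, avoidance),
then runs the full analysis path: GPS fixes -> per-cell distances -> entry
decisions -> choice table -> conditional-logit fit -> weighted permutation
test of the predictors as a whole.
"""

from gorillaspace import (
    SimConfig,
    UsageLedger,
    build_choice_table,
    distance_per_cell_table,
    extract_entry_decisions_table,
    fit_choice_model,
    permutation_full_null,
    simulate_movement,
)

cfg = SimConfig(seed=11, n_days=150, observed_fraction=1.0)
sim = simulate_movement(cfg)
grid = cfg.grid

visits = distance_per_cell_table(sim.fixes, grid)
decisions = extract_entry_decisions_table(sim.fixes, grid, sim.energy_field)
ledger = UsageLedger.from_cell_visits(visits, sim.group_sizes)
table = build_choice_table(decisions, sim.energy_field, ledger,
                           transform_states=sim.transform_states)

preds = ["food_z", "prev_self_z", "prev_nbr_z", "is_corner"]
fit = fit_choice_model(table, predictors=preds)
perm = permutation_full_null(table, n_perm=500, seed=12, predictors=preds)

print(f"{fit.n_sets} choice sets from {len(sim.fixes)} fixes")
print("coefficient (per sd of log predictor)   estimate    truth")
for name, truth in [("food_z", cfg.beta_food), ("prev_self_z", cfg.beta_self),
                    ("prev_nbr_z", cfg.beta_nbr)]:
    print(f"  {name:<36} {fit.coefficients[name]:+.3f}     {truth:+.2f}")
print(f"permutation full-null test: chi2 = {perm.observed_stat:.2f}, "
      f"p = {perm.p_value:.4f} ({perm.n_perm} permutations)")
print("Positive food and self-use coefficients mean groups prefer rich,")
print("familiar cells; the permutation p tests all predictors jointly.")
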