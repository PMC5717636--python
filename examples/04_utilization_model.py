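"""Utilization of a chosen area: mixed model with within/between split.

How far a group travels inside a cell (log distance) is modelled on food and
previous use, each split into within-group variation (day-to-day deviation
from the group's mean exposure) and between-group variation (the group
means), with random intercepts for group, cell and group x cell and a
residual autocorrelation smoother.
"""

from gorillaspace import run_utilization_analysis, simulate_utilization_rows

rows = simulate_utilization_rows(
    n_rows_total=400, seed=21,
    betas={"prev_self_within": 0.2, "prev_nbr_between": -0.5})
result = run_utilization_analysis(rows)

print(f"{len(rows)} visits from {rows['group'].nunique()} groups")
print("term                    estimate      se")
for name, est, se in zip(result.full.term_names, result.full.beta,
                         result.full.beta_se):
    print(f"  {name:<22} {est:+.3f}     {se:.3f}")
print("variance components:", {k: round(v, 3) for k, v in
                               result.full.variance_components.items()})
print(f"likelihood-ratio test of the 6 predictor terms: "
      f"chi2 = {result.lrt_stat:.2f}, df = {result.lrt_df}, "
      f"p = {result.lrt_p:.4f}")
print("A negative between-group neighbour term means groups whose cells are")
print("on average more used by neighbours travel less within them.")
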