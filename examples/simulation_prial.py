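"""A small replicated experiment: loss reduction from penalized estimation.

Runs 10 replicates of scenario A-I (five traits, equal heritability 0.4),
penalizing the log canonical eigenvalues with oracle tuning, and prints
the percentage reduction in average entropy loss (PRIAL) per covariance
matrix.  Equal population eigenvalues are the best case for this penalty.
"""

import penreml as pr

scen = pr.get_scenario("A-I")
summary = pr.run_experiment(
    scen,
    pr.SimConfig(s=100, n=10, replicates=10, seed=3),
    penalty=pr.PenaltySpec(kind="P_lambda_log"),
    strategy=pr.Strategy("Vinf"),
    psi_grid=pr.thin_grid(pr.build_psi_grid(), 8),
)

for comp in ("G", "E", "P"):
    print(f"sigma_{comp}: PRIAL = {summary.prial[comp]:5.1f}% "
          f"(se {summary.prial_se[comp]:.1f}), "
          f"replicates with increased loss: "
          f"{100 * summary.increased_loss_fraction[comp]:.0f}%")
print("mean chosen psi:", float(summary.psi_chosen.mean()))
# Large PRIALs for sigma_G and sigma_E, tiny for sigma_P: penalization
# redistributes the genetic/residual split but barely moves their sum.
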