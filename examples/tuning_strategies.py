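"""Comparing tuning-factor selection strategies on one dataset.

Fits a penalized path and selects psi by the population-parameter oracle
(V-infinity, available in simulations only), 3-fold cross-validation over
complete sire families, and the likelihood-drop limit — then scores each
choice against the known truth.
"""

import numpy as np

import penreml as pr

scen = pr.get_scenario("C-I")
cfg = pr.SimConfig(s=99, n=10)
data = pr.simulate_dataset(scen, cfg, rng=7)
spec = pr.PenaltySpec(kind="P_lambda_log2")
grid = pr.thin_grid(pr.build_psi_grid(), 8)

path = pr.fit_path(data, spec, grid)
choices = {
    "V-infinity": pr.choose_validation(path, pr.validation_stats(scen, cfg)),
    "CV3": pr.choose_cv(data, 3, spec, grid),
    "L5% rule": pr.choose_likelihood_limit(path),
}

loss0 = pr.entropy_loss(scen.truth.sigma_G, path.baseline.pair.sigma_G)
print(f"unpenalized entropy loss for sigma_G: {loss0:.3f}\n")
for label, choice in choices.items():
    est = path.fits[choice.index].pair.sigma_G
    loss = pr.entropy_loss(scen.truth.sigma_G, est)
    print(f"{label:12s} psi = {choice.psi_chosen:7.1f}  loss = {loss:.3f}  "
          f"reduction = {100 * (loss0 - loss) / loss0:5.1f}%")
# All three typically shrink; the oracle knows the truth, the data-driven
# strategies trade some of its gain for practicality.
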