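"""Fit effective enzyme rates to a synthetic observed profile by ABC.

A triplicate 'observed' profile is generated from the fit-demo ground truth
(3 cisternae, 5 enzymes, 15 rate parameters).  Rejection ABC then draws
rates from localization-informed priors, simulates a profile per proposal,
and accepts proposals whose score is at or below an adaptively shrinking
threshold (10% reduction whenever the recent acceptance rate exceeds 7%).
Budgets here are reduced for a quick demonstration run.
"""

import numpy as np

from glycosim import FitConfig, abc_rejection, gelman_rubin, make_scenario, synth_observed

scenario = make_scenario("fit-demo-3c", seed=7)
scenario.n_glycans = 2_000
observed = synth_observed(scenario)
truth = {f"{e}@{c}": r for (e, c), r in scenario.model().rates.items()}

cfg = FitConfig(
    target_accepted=400, n_chains=4, n_glycans_per_sim=2_000, seed=11,
    pilot=80, window=50, initial_quantile=0.75, final_quantile=0.35,
)
sample = abc_rejection(observed, scenario.priors, scenario.model(), cfg)

chains = sample.chains()
n_min = min(len(c) for c in chains)
r = gelman_rubin([c[:n_min] for c in chains])

print(f"accepted {len(sample.accepted)} draws in {sample.n_proposals} proposals "
      f"(final threshold {sample.final_threshold:.1f})")
print(f"max Gelman-Rubin R over {len(sample.param_names)} parameters: "
      f"{np.nanmax(r):.3f}")
print(f"{'parameter':12s} {'truth':>6s} {'post.mean':>9s} {'90% interval':>18s}")
arr = sample.as_array()
for j, name in enumerate(sample.param_names):
    lo, hi = sample.credible_interval(name, 0.9)
    print(f"{name:12s} {truth[name]:6.2f} {arr[:, j].mean():9.2f} "
          f"   [{lo:5.2f}, {hi:5.2f}]")

# Each ground-truth rate should fall inside its 90% credible interval for
# the strongly identified parameters; rates in cisternae where an enzyme
# barely acts stay close to their prior.
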