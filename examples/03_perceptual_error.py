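"""Perceptual error in the featureless-flanker condition.

With a no-gap flanker there is nothing to substitute or average, so report
errors stay centred on the target and the circular standard deviation of
the errors ("perceptual error") isolates positional/orientation
uncertainty. Bootstrap CIs resample trials.
"""

from crowdreport import (
    ExperimentDesign, ObserverModel, bootstrap_ci, circular_sd,
    simulate_experiment,
)

design = ExperimentDesign()
model = ObserverModel(p_target=1.0, noise_sd_deg=14.0)
trials = simulate_experiment(design, model, seed=77)

print("circular SD of report errors (deg) with 95% bootstrap CI:\n")
base = trials[trials.flanker_type == "unflanked"]
ci = bootstrap_ci(base["error_deg"].to_numpy(), circular_sd, seed=0)
print(f"unflanked        {ci.point:5.1f}  [{ci.lower:5.1f}, {ci.upper:5.1f}]")

no_gap = trials[trials.flanker_type == "no_gap"]
for sep, grp in no_gap.groupby("edge_separation_deg"):
    ci = bootstrap_ci(grp["error_deg"].to_numpy(), circular_sd, seed=0)
    print(f"no-gap sep {sep:4.2f}  {ci.point:5.1f}  [{ci.lower:5.1f}, {ci.upper:5.1f}]")

print("\nThis synthetic observer has separation-independent noise, so every "
      "condition fluctuates around the 14-deg generating SD (n = 100 each); "
      "a crowded human observer shows elevated values at small separations.")
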