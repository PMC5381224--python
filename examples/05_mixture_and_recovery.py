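"""Model-based estimators and their validation on known ground truth.

Fits the target/substitution/guess von Mises mixture and the Monte Carlo
grid estimator to one synthetic dataset, then runs a small recovery study
on the 100-trial two-component validation design — the same check the
analyses must pass before being trusted on real data. The averaging-
extended mixture's instability flag is expected to fire on most replicates.
"""

from crowdreport import (
    RecoveryScenario, fit_averaging_mixture, fit_standard_mixture,
    linear_slope, monte_carlo_proportions, run_recovery_study,
    simulate_validation_dataset,
)

df = simulate_validation_dataset(0.6, 0.4, noise_sd_deg=12.0,
                                 n_trials=1000, seed=5)
e, d = df["error_deg"], df["delta1_deg"]

fit = fit_standard_mixture(e, d, seed=0)
print("standard mixture on 1000 trials (truth: p_target .6, p_sub .4, SD 12):")
print(f"  p_target {fit.p_target:.3f}  p_sub {fit.p_substitution:.3f}  "
      f"p_guess {fit.p_guess:.3f}  SD {fit.circ_sd_deg:.1f} deg  "
      f"logL {fit.log_likelihood:.1f}")

mc = monte_carlo_proportions(e, d, noise_sd_deg=12.0, seed=0)
print(f"Monte Carlo grid:  p_target {mc.p_target:.2f}  "
      f"(Kuiper distance {mc.fit_score:.3f})")

avg = fit_averaging_mixture(e, d, seed=0)
print(f"averaging-extended: p_average {avg.p_average:.3f}  w {avg.average_weight:.2f}  "
      f"unstable={avg.unstable} (restart spread {avg.instability:.2f})")

slope = linear_slope(e, d)
print(f"linear slope: {slope.slope:.3f} — approaches the substitution share "
      f"(0.4) despite zero generative averaging; a slope-only analysis would "
      f"misread this as partial averaging")

print("\nrecovery study, 20 replicates of the 100-trial validation design:")
scn = RecoveryScenario(p_target=0.5, p_substitution=0.5, noise_sd_deg=10.0,
                       n_trials=100, n_replicates=20)
report = run_recovery_study([scn], seed=1)
cols = ["estimator", "mean_p_target", "mae_p_target", "unstable_fraction"]
print(report[cols].round(3).to_string(index=False))
print("\nMAE under 0.15 for labelling, the standard mixture and Monte Carlo "
      "means the estimators recover approximately the correct underlying "
      "proportions; the averaging-extended model is unreliable at this "
      "sample size (instability flag on nearly every replicate).")
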