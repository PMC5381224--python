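"""Stimulus geometry: conditions and flanker radii in Bouma units.

Enumerates the 16 target-flanker conditions and expresses each flanked
condition's spacing as the flanker's outer radius divided by the target
eccentricity — the dimensionless spacing that crowding strength tracks.
"""

from crowdreport import ExperimentDesign, enumerate_conditions

design = ExperimentDesign()
conditions = enumerate_conditions(design)

print(f"{len(conditions)} conditions "
      f"({design.reps_per_condition_per_session} reps x {design.n_sessions} "
      f"sessions = {design.n_trials_total} trials per observer)\n")
print(f"{'flanker type':<12} {'edge sep (deg)':>14} {'radius / ecc':>13}")
for cond in conditions:
    sep = "-" if cond.edge_separation_deg is None else f"{cond.edge_separation_deg:.2f}"
    r = cond.proportional_radius(design)
    radius = "-" if r is None else f"{r:.2f}"
    print(f"{cond.flanker_type:<12} {sep:>14} {radius:>13}")

print("\nSmaller radius = tighter flanker = stronger crowding; the largest "
      "radius (0.49) behaves almost like the unflanked baseline.")
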