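"""Quantify vehicle-normalised migration and ROS effects.

Builds a tiny zero-noise screen with one known enhancer and shows that the
recovered deltas match the planted activity: delta_migration is treated
minus vehicle endpoint closure, delta_ros the relative fluorescence change.
"""

from redoxscreen import CompoundTruth, SimConfig, quantify_screen, simulate_screen

truths = [
    CompoundTruth("enhancer-1", "enhancer", migration_effect=0.5,
                  ros_effect=-0.3, ec50=5.0, hill=1.0),
    CompoundTruth("inert-1", "neutral"),
]
ds = simulate_screen(SimConfig(n_compounds=2, seed=0, noise_sd=0.0), truths)
effects = quantify_screen(ds)

cols = ["compound_id", "cell_line", "dose_um", "delta_migration", "delta_ros",
        "p_migration", "toxic"]
s1 = effects[effects.screen == 1]
print(s1[cols].round(4).to_string(index=False))
print(
    "\ndelta_migration > 0: the compound closed the wound faster than the "
    "DMSO control;\ndelta_ros < 0: it lowered DCF fluorescence (antioxidant "
    "behaviour).  The neutral\ncompound sits at exactly 0 on both axes, and "
    "zero noise makes the rank-test\np-values uninformative by construction."
)
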