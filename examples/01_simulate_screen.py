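"""Simulate a small two-stage screen with planted compound activities.

A 10-compound library is screened in silico: stage 1 at 5 and 50 µM in one
cell line, stage 2 at 1/5/25/125 µM in four cell lines, quadruplicate
wells, wound images every 3 h for 24 h plus an endpoint ROS reading per
well.
"""

from redoxscreen import (
    SimConfig,
    default_truth_library,
    scaled_class_counts,
    simulate_screen,
)

truths = default_truth_library(seed=0, class_counts=scaled_class_counts(10))
config = SimConfig(n_compounds=10, seed=0)
ds = simulate_screen(config, truths)

print("planted ground truth:")
print(ds.truth[["compound_id", "class_label", "migration_effect", "ros_effect"]]
      .to_string(index=False))

print(f"\n{len(ds.timeseries):,} time-series rows, {len(ds.ros):,} ROS readings")

well = ds.wells(compound_id=truths[0].compound_id, dose_um=50.0)[0]
print(f"\nexample well {well.well} ({well.cell_line}, {well.dose:g} µM):")
for t, w in zip(well.times, well.wound_metric):
    print(f"  t={t:5.1f} h  wound open fraction = {w:.3f}")
print("(the wound-metric column is the fraction of the initial scratch still"
      " open; it decays toward 0 as cells migrate in)")
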