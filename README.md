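# redoxscreen

Analysis pipeline for two-stage phenotypic screens of redox-active
compounds in cancer cell lines, built around the observation that
antioxidants can *increase* melanoma cell migration while lowering
reactive-oxygen-species (ROS) levels. The package is aimed at groups
running plate-based wound-healing (scratch) assays and DCF-fluorescence
ROS assays who need a reproducible path from instrument exports to a
ranked hit list, plus the dose arithmetic to carry hits into a mouse
experiment.

## What it computes

**Assay quantification.** For a well with wound metric `w(t)` (fraction of
the initial scratch still open), endpoint closure is
`C = (w(0) − w(24 h)) / w(0)`. Each (compound, cell line, dose) group is
normalised against the DMSO vehicle wells on the same plate:

    Δmigration = mean C_treated − mean C_vehicle
    Δros       = (mean F_treated − mean F_vehicle) / mean F_vehicle

with DCF fluorescence `F`, a Wilcoxon–Mann–Whitney p-value per delta when
≥ 3 replicates exist, and a cytotoxicity flag when treated confluence falls
more than 20 % below vehicle (toxic compounds otherwise masquerade as
migration suppressors).

**Selection and ranking.** The primary screen (whole library, 2 doses, one
cell line) selects compounds with `Δmigration > ε` at both doses and no
toxicity flag. The confirmation screen (4 doses × 4 cell lines) scores
each compound 0/1 per grid cell on three criteria — increased migration
(max 16), decreased ROS (max 16), and dose-dependent effects on both (max
16 + 16 = 32) — and dense-ranks the totals (max 64): tied totals share a
rank label, the next distinct total takes the next integer.

**Dose translation.** Human RDA → mg/kg/day → ×12.3 metabolic scaling →
dose multipliers (5×, 50×) → chow concentration (mg/kg chow) or
drinking-water concentration (mg/ml) from daily intake and body weight.

**Synthetic screens.** A simulator generates complete screens (wound
trajectories `w(t) = exp(−k·t·m(dose))` under a Hill-curve rate multiplier
`m`, ROS endpoints, replicate noise, planted compound classes) so the whole
pipeline is testable against known ground truth.

## Worked example

```python
from redoxscreen import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1, output_dir="example_run"))
print(res["ranked"].head(3).to_string(index=False))
```

```
 rank compound_id               common_name other_name  migration_max16  ros_max16  dose_response_max32  total_max64
    1    enzo-053 Redox library compound 53                          16         16                   31           63
    1    enzo-069 Redox library compound 69                          16         16                   31           63
    1    enzo-076 Redox library compound 76                          16         16                   31           63
```

This simulates the default 104-compound library (27 planted migration
enhancers with antioxidant activity), selects 27 primary-screen hits, and
ranks their scorecards; the three compounds tied at 63/64 share rank 1.
The same run from the shell:

```
redoxscreen run --seed 1 --out example_run
redoxscreen dose --compound vitamin-c --route water --base 90 --output dose.tsv
```

The `examples/` directory has one short script per capability
(simulation, quantification, selection + ranking, reference-scorecard
arithmetic, dose translation).

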