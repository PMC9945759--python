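# Methods

## Scope and data model

The package analyses two-stage phenotypic screens of redox-active
compounds: a primary screen of a whole library at two doses in one cell
line, then a confirmation screen of the survivors at four doses in four
cell lines, with a scratch-wound migration readout and an endpoint DCF
(2′,7′-dichlorofluorescein) fluorescence readout per well. Analysis starts
from well-level tables (a wound-metric time series and one fluorescence
value per well); instrument image segmentation is upstream of the package
and is emulated only inside the simulator.

The wound metric is defined here as the fraction of the initial wound area
still open, in [0, 1], with the first post-scratch timepoint as baseline.
Wound-imaging platforms report several related quantities (wound
confluence, relative wound density); any monotone per-well scalar can be
fed through the same vehicle-delta contract, which is also how trans-well
invasion areas can be analysed without dedicated support.

## Vehicle normalisation

Effects are always deltas against DMSO vehicle wells on the *same plate*
(and hence the same cell line): plate-to-plate offsets in seeding density
or reader gain cancel in the migration difference and approximately in the
relative ROS change. Replicates aggregate by mean (median available for
robustness). Closure uses the nearest recorded timepoint within 1.5 h of
the requested endpoint (default 24 h, matching one day of compound
exposure); a series without such a timepoint is an error, never silently
extrapolated. A group compared against itself yields exactly zero deltas
by construction — this is asserted, not approximated, in the tests.

Two-group Wilcoxon–Mann–Whitney p-values are attached whenever both groups
have ≥ 3 replicates. They are reported but do **not** gate the binary
scoring by default: a direction-plus-threshold call is the primary
criterion, and an optional p < 0.05 gate (`significance_gate`) can only
remove points, never add them. With quadruplicate wells the exact
Mann–Whitney p-value cannot fall below ≈ 0.03, so gating at n = 4 is
deliberately conservative.

## Cytotoxicity

Cytotoxic compounds depress the migration readout because cells die, not
because they migrate less. Toxicity is therefore called from the separate
confluence channel: a treated group whose endpoint confluence falls more
than `toxicity_threshold` (default 0.2, i.e. 20 % of vehicle) below the
vehicle is flagged, reported with its migration delta, and excluded from
primary-screen selection. Without a confluence channel the call degrades
to wound-metric pathology (the wound re-opening after its minimum, a
signature of detaching cells) and the downgrade is logged.

## Selection and scoring

**Primary screen.** A compound is selected when Δmigration > ε at *both*
screening doses and it is not flagged toxic. ε defaults to 0.02 — one
replicate-noise standard deviation of the wound metric under the default
assay model — so that directional calls below the assay noise floor are
not counted as hits. The low-level `score_binary`/`select_first_screen`
functions accept any ε (including 0, pure direction).

**Confirmation scorecard.** Over the 4 cell lines × 4 doses grid, per
assay: a directional point per cell (migration up / ROS down beyond ε, max
16 each) and a dose-response point per cell. The dose-response rule is a
monotone-consistency criterion: a cell scores 1 iff its directional call
holds *and* its effect magnitude in the scored direction has not shrunk
from the next-lower dose by more than `tolerance` (default 0.01); the
lowest dose scores on its directional call alone. This rule was chosen
because it allocates exactly one point per (cell line, dose, assay),
matching the 16 + 16 budget; it is a package convention, since only the
point budget of the original scoring is recorded, not the per-cell
criterion. Missing grid cells — and cells whose next-lower neighbour is
missing — conservatively score 0 with a logged warning, never imputed.

**Ranking.** Totals (max 64) are dense-ranked descending: tied totals
share one rank label and the next distinct total takes the next integer
(so 18 compounds can carry 12 labels). Within a tied rank, cards are
presented by migration subscore descending, then name — a deterministic
display order that does not affect the labels. The packaged reference
scorecard of 18 compounds reproduces its printed totals from its printed
components for every row except GSH, whose printed components sum to 22
against a printed total of 26; that row is carried as printed and excluded
from component-sum checks rather than silently corrected.

## Dose translation

Chow route: supplemented concentration = chow RDA content × multiplier
(e.g. β-carotene 7.2 mg/kg chow × {5, 50} = {36, 360}). Water route:
human RDA / body mass (reported to 3 decimals) × metabolic factor 12.3
(reported to 2 decimals) × multiplier, then a rounding rule, then
concentration = daily dose × body weight / water intake (defaults 10
ml/day; 25 g male, 18 g female, computed separately per sex since a pooled
weight is not recorded). The metabolic factor is treated as an opaque
constant. The default rounding rule is *ceil to the nearest 10 mg/kg/day*
(79.1 → 80, 791 → 800): it is the only simple rule consistent with the
published dosing levels the chain is checked against (half-up rounding
would give 790, not 800); it is named in every emitted plan and
configurable (`none` disables it).

## Simulator

The generator exists to give every downstream stage a ground truth. One
closure-rate parameter carries all compound effects: the fraction of wound
open is `exp(−k·t·m)` with baseline rate k = 0.04 h⁻¹ (vehicle closes
~62 % in 24 h, typical of a motile melanoma line) and

    m(dose) = v(dose) · (1 + e_mig · h(dose)),      h = dose^n / (dose^n + EC50^n),
    v(dose) = 1 − (1 − viability) · h(dose),

with ROS fluorescence `baseline · v · (1 + e_ros · h)`. Planted classes:
27 enhancers (e_mig ∈ U(0.3, 0.7), antioxidant e_ros ∈ U(−0.5, −0.15)),
20 suppressors, 15 toxic (viability U(0.4, 0.7), masquerading as
suppressors), 10 prooxidants, 32 neutral — 104 total, sized so the planted
hit set matches the scale of the screen modelled. EC50s are log-uniform
over 2–10 µM (both primary doses on the responsive part of the curve),
Hill slopes uniform over 1–2. Noise is additive Gaussian (σ = 0.02 on the
wound metric and on relative fluorescence), truncated to valid ranges,
replicate-level; an optional per-plate additive offset exercises the
per-plate normalisation. The t = 0 sample is pinned at exactly 1 because
the metric is defined relative to the initial wound. The effect ranges and
ε = 0.02 were fixed together from a design-stage power calculation
(expected selection sensitivity and specificity ≥ 0.99 at four replicates;
worst-case zero-noise planted delta 0.0214 > ε analytically), before any
recovery experiment was run.

What the simulator does *not* emulate: spatial plate effects and edge
wells, cell-cycle or density-dependent closure kinetics, dye-loading
variability, optical crosstalk, or compound degradation over 24 h. Passing
recovery tests therefore shows the analysis is correct under its own
stated noise model, not that real screens achieve these operating
characteristics.

## Numerical conventions

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configuration yields bit-identical
datasets and byte-identical output files. Tables are comma-separated
UTF-8 with `#` comments and a header; doses are µM everywhere and a
`dose_unit` column with any other unit is rejected rather than converted.
Dense ranking, subscore sums and self-control deltas are integer/exact
arithmetic; closed-form recovery tests assert to 1e-12. A well whose
baseline wound is already 0 closes nothing and scores 0 rather than
dividing by zero; vehicle fluorescence aggregating to 0 is an error.

## Problem sizes

The default simulated screen is 104 compounds × (1 cell line × 2 doses +
4 cell lines × 4 doses) × 4 replicates ≈ 7,600 wells at 9 timepoints
(~68,000 rows), which simulates in well under a second and quantifies in a
few seconds; the oracle cross-check of the dose-response scorer uses 1,000
random 4 × 4 grids. These sizes keep the complete validation suite and the
reproduction script comfortably interactive.
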