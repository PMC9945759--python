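"""Synthetic two-stage screen generator.

Generates complete screen datasets — wound-healing time-series plus endpoint
DCF fluorescence readings — with planted ground-truth compound classes, so
the whole quantify → select → score → rank pipeline can be exercised and
validated without wet-lab data.

Kinetic model
-------------
A scratch wound closes by a saturating-exponential law: the fraction of the
initial wound still open at time ``t`` hours is ``exp(-k * t * m)`` where
``k`` is the vehicle closure rate (per hour) and ``m`` a compound- and
dose-specific rate multiplier,

    m(dose) = viability(dose) * (1 + migration_effect * h(dose)),
    h(dose) = dose**hill / (dose**hill + ec50**hill),
    viability(dose) = 1 - (1 - viability) * h(dose).

DCF fluorescence is ``baseline * viability(dose) * (1 + ros_effect *
h(dose))``.  Vehicle (DMSO) wells follow the same laws with all effects
zero.  Replicate noise is additive Gaussian, truncated to the metric's valid
range; an optional per-plate additive offset exercises the per-plate vehicle
normalisation downstream.

Cytotoxic compounds (viability < 1) depress closure and fluorescence
together, so in the migration readout they masquerade as suppressors — the
confluence channel is what separates them.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    VEHICLE,
    CompoundTruth,
    ScreenDataset,
    SimConfig,
    ValidationError,
)

__all__ = [
    "hill_response",
    "rate_multiplier",
    "default_truth_library",
    "scaled_class_counts",
    "simulate_screen",
]


def hill_response(dose: np.ndarray | float, ec50: float, hill: float):
    """Fractional Hill occupancy ``dose**h / (dose**h + ec50**h)``."""
    d = np.asarray(dose, dtype=float)
    return d**hill / (d**hill + ec50**hill)


def rate_multiplier(truth: CompoundTruth, dose: float) -> float:
    """Closure-rate multiplier for one compound at one dose (noise-free)."""
    h = float(hill_response(dose, truth.ec50, truth.hill))
    viab = 1.0 - (1.0 - truth.viability) * h
    return viab * (1.0 + truth.migration_effect * h)


# Class mix of the default simulated library: sized so the primary screen's
# planted hit set matches the scale of the screen this pipeline models
# (27 migration enhancers among 104 compounds).
_DEFAULT_CLASS_COUNTS = {
    "enhancer": 27,
    "suppressor": 20,
    "toxic": 15,
    "prooxidant": 10,
    "neutral": 32,
}


def scaled_class_counts(n: int) -> dict[str, int]:
    """Shrink the default class mix to ``n`` compounds, preserving the
    ratios (the remainder lands in the neutral class)."""
    total = sum(_DEFAULT_CLASS_COUNTS.values())
    counts = {k: round(v * n / total) for k, v in _DEFAULT_CLASS_COUNTS.items()}
    counts["neutral"] += n - sum(counts.values())
    return counts


def default_truth_library(
    compound_ids: Optional[Sequence[str]] = None,
    seed: int = 0,
    class_counts: Optional[dict[str, int]] = None,
) -> list[CompoundTruth]:
    """Draw a ground-truth activity table for a simulated library.

    Enhancers get a migration boost of 30-70% of the closure rate at
    saturation together with antioxidant activity (15-50% fluorescence
    drop); suppressors slow closure by 30-60%; toxic compounds kill 30-60%
    of cells at saturation; prooxidants raise fluorescence 20-60%.  EC50s
    are log-uniform over 2-10 µM so both primary-screen doses sit on the
    responsive part of the curve; Hill slopes are uniform over 1-2.
    """
    counts = dict(class_counts or _DEFAULT_CLASS_COUNTS)
    n = sum(counts.values())
    if compound_ids is None:
        compound_ids = [f"cmpd-{i + 1:03d}" for i in range(n)]
    if len(compound_ids) != n:
        raise ValidationError(
            f"compound_ids: got {len(compound_ids)} ids for {n} class slots"
        )
    rng = np.random.default_rng(seed)
    labels = [c for c, k in counts.items() for _ in range(k)]
    rng.shuffle(labels)

    truths = []
    for cid, label in zip(compound_ids, labels):
        ec50 = float(np.exp(rng.uniform(np.log(2.0), np.log(10.0))))
        hill = float(rng.uniform(1.0, 2.0))
        mig, ros, viab = 0.0, 0.0, 1.0
        if label == "enhancer":
            mig = float(rng.uniform(0.3, 0.7))
            ros = -float(rng.uniform(0.15, 0.5))
        elif label == "suppressor":
            mig = -float(rng.uniform(0.3, 0.6))
        elif label == "toxic":
            viab = float(rng.uniform(0.4, 0.7))
        elif label == "prooxidant":
            ros = float(rng.uniform(0.2, 0.6))
        truths.append(
            CompoundTruth(
                compound_id=str(cid),
                class_label=label,
                migration_effect=mig,
                ros_effect=ros,
                ec50=ec50,
                hill=hill,
                viability=viab,
            )
        )
    return truths


def _screen_grid(
    config: SimConfig, compound_ids: Sequence[str]
) -> pd.DataFrame:
    """One row per well over both screen stages, vehicle wells included."""
    frames = []
    stages = [
        (1, [config.cell_lines[0]], list(config.doses_screen1)),
        (2, list(config.cell_lines), list(config.doses_screen2)),
    ]
    reps = range(1, config.n_replicates + 1)
    for screen, lines, doses in stages:
        for line in lines:
            for dose in doses:
                plate = f"S{screen}-{line}-{dose:g}uM"
                rows = [
                    (plate, f"{cid}-r{rep}", screen, line, cid, dose, rep)
                    for cid in compound_ids
                    for rep in reps
                ]
                # matched DMSO wells on every plate; dose recorded as 0
                rows += [
                    (plate, f"{VEHICLE}-r{rep}", screen, line, VEHICLE, 0.0, rep)
                    for rep in reps
                ]
                frames.append(
                    pd.DataFrame(
                        rows,
                        columns=[
                            "plate_id",
                            "well",
                            "screen",
                            "cell_line",
                            "compound_id",
                            "dose_um",
                            "replicate",
                        ],
                    )
                )
    return pd.concat(frames, ignore_index=True)


def simulate_screen(
    config: SimConfig, truths: Sequence[CompoundTruth]
) -> ScreenDataset:
    """Simulate a full two-stage screen for the given ground truth.

    Returns a :class:`ScreenDataset` whose ``timeseries`` table holds one
    wound-metric trajectory per (compound, cell line, dose, replicate) well
    plus matched vehicle wells per plate, and whose ``ros`` table holds one
    endpoint fluorescence reading per such well.  Identical ``(config,
    truths)`` always yield a bit-identical dataset (the seed lives in the
    config).
    """
    truths = list(truths)
    if len(truths) != config.n_compounds:
        raise ValidationError(
            f"truths: expected {config.n_compounds} entries "
            f"(config.n_compounds), got {len(truths)}"
        )
    ids = [t.compound_id for t in truths]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValidationError(f"compound_id: duplicate ids {sorted(dupes)}")

    by_id = {t.compound_id: t for t in truths}
    vehicle_truth = CompoundTruth(VEHICLE, "neutral")
    wells = _screen_grid(config, ids)

    # Noise-free per-well signals.
    mult = np.empty(len(wells))
    viab = np.empty(len(wells))
    ros_mean = np.empty(len(wells))
    for i, r in enumerate(wells.itertuples()):
        t = vehicle_truth if r.compound_id == VEHICLE else by_id[r.compound_id]
        h = float(hill_response(r.dose_um, t.ec50, t.hill)) if r.dose_um > 0 else 0.0
        v = 1.0 - (1.0 - t.viability) * h
        mult[i] = v * (1.0 + t.migration_effect * h)
        viab[i] = v
        ros_mean[i] = config.ros_baseline * v * (1.0 + t.ros_effect * h)

    rng = np.random.default_rng(config.seed)
    plate_ids = wells["plate_id"].to_numpy()
    plates = pd.unique(plate_ids)
    offsets = dict(
        zip(plates, rng.normal(0.0, config.plate_offset_sd, size=len(plates)))
        if config.plate_offset_sd > 0
        else zip(plates, np.zeros(len(plates)))
    )
    well_offset = np.array([offsets[p] for p in plate_ids])

    times = np.asarray(config.timepoints, dtype=float)
    k = config.baseline_rate
    # wound fraction open: exp(-k * t * m); t=0 column pinned at exactly 1
    # (the metric is defined relative to the initial wound).
    open_frac = np.exp(-k * np.outer(mult, times))
    noise = rng.normal(0.0, config.noise_sd, size=open_frac.shape)
    noise[:, times == 0.0] = 0.0
    wound = np.clip(open_frac + noise + well_offset[:, None] * (times > 0), 0.0, 1.0)

    confl_mean = config.baseline_confluence * viab
    confl_noise = rng.normal(0.0, config.noise_sd, size=open_frac.shape)
    confluence = np.clip(confl_mean[:, None] + confl_noise, 0.0, 1.0)

    ros_noise = rng.normal(0.0, config.noise_sd * config.ros_baseline, size=len(wells))
    fluorescence = np.maximum(
        ros_mean + ros_noise + well_offset * config.ros_baseline, 0.0
    )

    n_t = len(times)
    ts = wells.loc[wells.index.repeat(n_t)].reset_index(drop=True)
    ts["time_h"] = np.tile(times, len(wells))
    ts["wound_metric"] = wound.ravel()
    ts["confluence"] = confluence.ravel()

    ros = wells.copy()
    ros["fluorescence"] = fluorescence

    truth_df = pd.DataFrame(
        [
            {
                "compound_id": t.compound_id,
                "class_label": t.class_label,
                "migration_effect": t.migration_effect,
                "ros_effect": t.ros_effect,
                "ec50_um": t.ec50,
                "hill": t.hill,
                "viability": t.viability,
            }
            for t in truths
        ]
    )
    return ScreenDataset(timeseries=ts, ros=ros, truth=truth_df, config=config)
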