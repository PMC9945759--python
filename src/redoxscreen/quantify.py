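"""Vehicle-normalised quantification of wound-healing and ROS assays.

Turns raw well-level measurements into per-(compound, cell line, dose)
effect estimates against matched DMSO controls:

* :func:`wound_closure` — endpoint closure fraction of one well;
* :func:`effect_vs_control` — migration and ROS deltas for one treated
  group against its per-plate vehicle group;
* :func:`flag_toxicity` — cytotoxicity call from the confluence channel;
* :func:`quantify_screen` — the vectorised table-level driver.

Closure of a well is ``(baseline wound - wound at endpoint) / baseline
wound``; the migration delta is mean treated closure minus mean vehicle
closure, and the ROS delta is the relative change in mean fluorescence.
Vehicle matching is always within a plate (and hence within a cell line).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    VEHICLE,
    EffectEstimate,
    RosReading,
    ScreenDataset,
    ValidationError,
    WellTimeSeries,
)

__all__ = [
    "wound_closure",
    "effect_vs_control",
    "flag_toxicity",
    "quantify_screen",
]

logger = logging.getLogger(__name__)

#: Endpoint used throughout unless overridden: 24 h of compound exposure.
DEFAULT_ENDPOINT_H = 24.0

#: How far (hours) the nearest recorded timepoint may sit from the requested
#: endpoint before lookup is refused.
ENDPOINT_TOLERANCE_H = 1.5


def wound_closure(
    series: WellTimeSeries,
    endpoint: float = DEFAULT_ENDPOINT_H,
    tolerance: float = ENDPOINT_TOLERANCE_H,
) -> float:
    """Fraction of the initial wound closed by ``endpoint`` hours.

    Uses the nearest recorded timepoint within ``tolerance`` hours of the
    requested endpoint.  A well whose wound was already closed at baseline
    (baseline metric 0) has nothing to close and scores 0.
    """
    idx = int(np.argmin(np.abs(series.times - endpoint)))
    if abs(series.times[idx] - endpoint) > tolerance:
        raise ValidationError(
            f"well {series.well}: no timepoint within {tolerance} h of "
            f"endpoint {endpoint} h (nearest: {series.times[idx]} h)"
        )
    baseline = series.wound_metric[0]
    if baseline == 0:
        return 0.0
    return float((baseline - series.wound_metric[idx]) / baseline)


def _aggregate(values: np.ndarray, agg: str) -> float:
    if agg == "mean":
        return float(np.mean(values))
    if agg == "median":
        return float(np.median(values))
    raise ValidationError(f"unknown replicate aggregation {agg!r}")


def _delta_stats(
    treated: np.ndarray, vehicle: np.ndarray, agg: str
) -> tuple[float, float, Optional[float]]:
    """Delta of aggregates, its standard error, and a two-sided
    Wilcoxon-Mann-Whitney p-value when both groups have >= 3 replicates."""
    delta = _aggregate(treated, agg) - _aggregate(vehicle, agg)
    if len(treated) > 1 and len(vehicle) > 1:
        sd = float(
            np.sqrt(
                np.var(treated, ddof=1) / len(treated)
                + np.var(vehicle, ddof=1) / len(vehicle)
            )
        )
    else:
        sd = float("nan")
    p = None
    if len(treated) >= 3 and len(vehicle) >= 3:
        if np.ptp(treated) == 0 and np.ptp(vehicle) == 0 and treated[0] == vehicle[0]:
            p = 1.0  # all observations identical: no evidence either way
        else:
            p = float(
                stats.mannwhitneyu(treated, vehicle, alternative="two-sided").pvalue
            )
    return delta, sd, p


def _check_groups(
    treated: Sequence[WellTimeSeries], vehicle: Sequence[WellTimeSeries]
) -> None:
    if not treated or not vehicle:
        raise ValidationError("treated and vehicle groups must be non-empty")
    lines = {s.cell_line for s in treated} | {s.cell_line for s in vehicle}
    if len(lines) > 1:
        raise ValidationError(f"groups span multiple cell lines: {sorted(lines)}")
    t_plates = {s.plate_id for s in treated}
    v_plates = {s.plate_id for s in vehicle}
    if t_plates != v_plates:
        raise ValidationError(
            f"mismatched plates: treated on {sorted(t_plates)}, "
            f"vehicle on {sorted(v_plates)}"
        )


def flag_toxicity(
    treated: Sequence[WellTimeSeries],
    vehicle: Sequence[WellTimeSeries],
    threshold: float = 0.2,
    endpoint: float = DEFAULT_ENDPOINT_H,
    agg: str = "mean",
) -> bool:
    """Flag a treated group as cytotoxic.

    True when the endpoint confluence (overall cell cover) falls below the
    vehicle group's by more than ``threshold`` as a fraction of vehicle.
    Without a confluence channel the call degrades to wound-metric pathology
    — substantial re-opening of the wound after its minimum — and the
    downgrade is logged.
    """
    _check_groups(treated, vehicle)

    def endpoint_confluence(s: WellTimeSeries) -> Optional[float]:
        if s.confluence is None:
            return None
        idx = int(np.argmin(np.abs(s.times - endpoint)))
        return float(s.confluence[idx])

    t_conf = [endpoint_confluence(s) for s in treated]
    v_conf = [endpoint_confluence(s) for s in vehicle]
    if None not in t_conf and None not in v_conf:
        v_mean = _aggregate(np.asarray(v_conf, float), agg)
        if v_mean == 0:
            return False
        t_mean = _aggregate(np.asarray(t_conf, float), agg)
        return (v_mean - t_mean) / v_mean > threshold

    logger.warning(
        "no confluence channel for %s: toxicity assessed from wound-metric "
        "pathology only",
        treated[0].compound_id,
    )
    # Re-opening: the wound metric rising back above its minimum by more
    # than `threshold` of the baseline indicates cells detaching.
    reopen = [float(s.wound_metric[-1] - s.wound_metric.min()) for s in treated]
    return _aggregate(np.asarray(reopen, float), agg) > threshold


def effect_vs_control(
    treated: Sequence[WellTimeSeries],
    vehicle: Sequence[WellTimeSeries],
    ros_treated: Sequence[RosReading],
    ros_vehicle: Sequence[RosReading],
    endpoint: float = DEFAULT_ENDPOINT_H,
    agg: str = "mean",
    toxicity_threshold: float = 0.2,
) -> EffectEstimate:
    """Estimate one (compound, cell line, dose) group's effects.

    ``delta_migration`` = aggregate treated closure - aggregate vehicle
    closure; ``delta_ros`` = (aggregate F_treated - aggregate F_vehicle) /
    aggregate F_vehicle.  Wilcoxon-Mann-Whitney p-values are attached when
    both groups have at least 3 replicates.
    """
    _check_groups(treated, vehicle)
    t_clo = np.array([wound_closure(s, endpoint) for s in treated])
    v_clo = np.array([wound_closure(s, endpoint) for s in vehicle])
    d_mig, sd_mig, p_mig = _delta_stats(t_clo, v_clo, agg)

    t_f = np.array([r.fluorescence for r in ros_treated])
    v_f = np.array([r.fluorescence for r in ros_vehicle])
    if t_f.size == 0 or v_f.size == 0:
        raise ValidationError("ROS groups must be non-empty")
    v_mean = _aggregate(v_f, agg)
    if v_mean == 0:
        raise ValidationError(
            f"vehicle fluorescence aggregates to 0 on plate "
            f"{vehicle[0].plate_id}: ROS delta undefined"
        )
    d_f, sd_f, p_ros = _delta_stats(t_f, v_f, agg)
    d_ros = d_f / v_mean
    sd_ros = sd_f / v_mean if np.isfinite(sd_f) else float("nan")

    return EffectEstimate(
        compound_id=treated[0].compound_id,
        cell_line=treated[0].cell_line,
        dose=treated[0].dose,
        delta_migration=d_mig,
        delta_ros=d_ros,
        n_replicates=len(treated),
        sd_migration=sd_mig,
        sd_ros=sd_ros,
        p_migration=p_mig,
        p_ros=p_ros,
        toxic=flag_toxicity(treated, vehicle, toxicity_threshold, endpoint, agg),
    )


def _per_well_endpoint(
    ts: pd.DataFrame, endpoint: float, tolerance: float
) -> pd.DataFrame:
    """Collapse the long time-series table to one row per well with its
    baseline wound, endpoint wound, closure and endpoint confluence."""
    keys = ["plate_id", "well"]
    ts = ts.sort_values(keys + ["time_h"], kind="stable")
    first = ts.groupby(keys, sort=False).first()

    dist = (ts["time_h"] - endpoint).abs()
    near_idx = dist.groupby([ts[k] for k in keys], sort=False).idxmin()
    near = ts.loc[near_idx].set_index(keys)
    off = (near["time_h"] - endpoint).abs()
    bad = off[off > tolerance]
    if len(bad):
        plate, well = bad.index[0]
        raise ValidationError(
            f"well {well} on {plate}: no timepoint within {tolerance} h of "
            f"endpoint {endpoint} h"
        )

    out = first[
        [c for c in ("screen", "cell_line", "compound_id", "dose_um", "replicate") if c in first]
    ].copy()
    base = first["wound_metric"]
    out["closure"] = np.where(
        base > 0, (base - near["wound_metric"]) / base.replace(0, np.nan), 0.0
    )
    out["confluence_end"] = (
        near["confluence"] if "confluence" in near else np.nan
    )
    return out.reset_index()


def quantify_screen(
    dataset: ScreenDataset,
    endpoint: float = DEFAULT_ENDPOINT_H,
    tolerance: float = ENDPOINT_TOLERANCE_H,
    agg: str = "mean",
    toxicity_threshold: float = 0.2,
    compute_pvalues: bool = True,
) -> pd.DataFrame:
    """Quantify every (compound, cell line, dose) group in a screen dataset.

    Returns one row per group with columns ``screen, compound_id,
    cell_line, dose_um, delta_migration, sd_migration, p_migration,
    delta_ros, sd_ros, p_ros, n_replicates, toxic``.  Vehicle wells are
    matched within each plate.
    """
    wells = _per_well_endpoint(dataset.timeseries, endpoint, tolerance)
    ros = dataset.ros

    rows = []
    for plate, pw in wells.groupby("plate_id", sort=True):
        veh = pw[pw["compound_id"] == VEHICLE]
        if veh.empty:
            raise ValidationError(f"plate {plate}: no vehicle (DMSO) wells")
        pr = ros[ros["plate_id"] == plate]
        veh_ros = pr[pr["compound_id"] == VEHICLE]["fluorescence"].to_numpy()
        if veh_ros.size == 0:
            raise ValidationError(f"plate {plate}: no vehicle ROS readings")
        v_clo = veh["closure"].to_numpy()
        v_conf = veh["confluence_end"].to_numpy()
        v_f_mean = _aggregate(veh_ros, agg)
        if v_f_mean == 0:
            raise ValidationError(
                f"plate {plate}: vehicle fluorescence aggregates to 0"
            )
        has_conf = not np.isnan(v_conf).any()

        for (cid, dose), grp in pw[pw["compound_id"] != VEHICLE].groupby(
            ["compound_id", "dose_um"], sort=True
        ):
            t_clo = grp["closure"].to_numpy()
            d_mig, sd_mig, p_mig = _delta_stats(t_clo, v_clo, agg)
            t_f = pr[(pr["compound_id"] == cid) & (pr["dose_um"] == dose)][
                "fluorescence"
            ].to_numpy()
            if t_f.size == 0:
                logger.warning(
                    "plate %s: no ROS readings for %s at %g uM", plate, cid, dose
                )
                d_ros, sd_ros, p_ros = np.nan, np.nan, None
            else:
                d_f, sd_f, p_ros = _delta_stats(t_f, veh_ros, agg)
                d_ros = d_f / v_f_mean
                sd_ros = sd_f / v_f_mean if np.isfinite(sd_f) else np.nan
            if has_conf:
                t_conf = _aggregate(grp["confluence_end"].to_numpy(), agg)
                v_conf_a = _aggregate(v_conf, agg)
                toxic = (
                    v_conf_a > 0
                    and (v_conf_a - t_conf) / v_conf_a > toxicity_threshold
                )
            else:
                toxic = False
            rows.append(
                {
                    "screen": grp["screen"].iloc[0] if "screen" in grp else np.nan,
                    "compound_id": cid,
                    "cell_line": grp["cell_line"].iloc[0],
                    "dose_um": float(dose),
                    "delta_migration": d_mig,
                    "sd_migration": sd_mig,
                    "p_migration": p_mig if compute_pvalues else np.nan,
                    "delta_ros": d_ros,
                    "sd_ros": sd_ros,
                    "p_ros": p_ros if compute_pvalues else np.nan,
                    "n_replicates": len(grp),
                    "toxic": bool(toxic),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["screen", "compound_id", "cell_line", "dose_um"], kind="stable"
    ).reset_index(drop=True)
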