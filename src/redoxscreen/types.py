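"""Core domain types for the redox-compound screen pipeline.

The pipeline revolves around a handful of small records:

* :class:`WellTimeSeries` — one well's wound-metric trajectory with its full
  experimental coordinates (cell line, compound, dose, replicate).
* :class:`RosReading` — one well's endpoint DCF fluorescence.
* :class:`EffectEstimate` — vehicle-normalised migration and ROS deltas for
  one (compound, cell line, dose) group.
* :class:`ScoreCard` — a compound's 0/1 score matrices, subscores, total and
  dense rank.
* :class:`MouseDoseSpec` / :class:`AnimalModel` — mouse dosing plans.
* :class:`CompoundTruth` / :class:`SimConfig` — simulator ground truth and
  configuration.

Bulk data (whole screens) travels as :class:`pandas.DataFrame` tables inside
:class:`ScreenDataset`; the records above are the per-item views the
quantification and scoring operations are defined on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: compound_id used for solvent-only (DMSO) control wells.
VEHICLE = "VEHICLE"

#: Compound classes the simulator can plant.
COMPOUND_CLASSES = ("enhancer", "suppressor", "neutral", "toxic", "prooxidant")


class ValidationError(ValueError):
    """Raised when an input record or table violates its contract."""


@dataclass(frozen=True)
class CompoundTruth:
    """Ground-truth activity of one simulated compound.

    ``migration_effect`` and ``ros_effect`` are the maximal fractional
    changes (at saturating dose) of the wound-closure rate and of DCF
    fluorescence; the dose-response follows a Hill curve with midpoint
    ``ec50`` (µM) and slope ``hill``.  ``viability`` is the surviving cell
    fraction at saturating dose; values below 1 mark cytotoxic compounds,
    which depress both closure and fluorescence and thereby masquerade as
    migration suppressors.
    """

    compound_id: str
    class_label: str
    migration_effect: float = 0.0
    ros_effect: float = 0.0
    ec50: float = 5.0
    hill: float = 1.0
    viability: float = 1.0

    def __post_init__(self) -> None:
        if self.class_label not in COMPOUND_CLASSES:
            raise ValidationError(
                f"class_label {self.class_label!r} for {self.compound_id}: "
                f"must be one of {COMPOUND_CLASSES}"
            )
        if not self.ec50 > 0:
            raise ValidationError(f"ec50 must be > 0 (compound {self.compound_id})")
        if not self.hill > 0:
            raise ValidationError(f"hill must be > 0 (compound {self.compound_id})")
        if not 0 < self.viability <= 1:
            raise ValidationError(
                f"viability must be in (0, 1] (compound {self.compound_id})"
            )
        if self.class_label == "neutral" and (
            self.migration_effect != 0 or self.ros_effect != 0
        ):
            raise ValidationError(
                f"neutral compound {self.compound_id} must have zero effects"
            )


#: Default hours grid: images every 3 h for 24 h after the scratch.
DEFAULT_TIMEPOINTS = tuple(float(t) for t in range(0, 25, 3))

#: The four melanoma lines of the confirmation screen; the first (an
#: NRAS-mutant line) is the single line used in the primary screen.
DEFAULT_CELL_LINES = ("SK-MEL-30", "IPC-298", "SK-MEL-3", "A-375")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated two-stage screen.

    Defaults mirror the screen design this pipeline models: a primary screen
    of the whole library at 5 and 50 µM in one cell line, then a
    confirmation screen at 1/5/25/125 µM in four cell lines, in
    quadruplicate, read over 24 h.
    """

    n_compounds: int = 104
    cell_lines: Sequence[str] = DEFAULT_CELL_LINES
    doses_screen1: Sequence[float] = (5.0, 50.0)
    doses_screen2: Sequence[float] = (1.0, 5.0, 25.0, 125.0)
    n_replicates: int = 4
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    noise_sd: float = 0.02
    baseline_rate: float = 0.04
    ros_baseline: float = 1000.0
    baseline_confluence: float = 0.9
    plate_offset_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("doses_screen1", "doses_screen2"):
            doses = list(getattr(self, name))
            if any(d <= 0 for d in doses):
                raise ValidationError(f"{name}: doses must be strictly positive")
            if any(b <= a for a, b in zip(doses, doses[1:])):
                raise ValidationError(f"{name}: doses must be strictly increasing")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.plate_offset_sd < 0:
            raise ValidationError("plate_offset_sd must be >= 0")
        times = list(self.timepoints)
        if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("timepoints must be >= 2 strictly increasing hours")
        if self.baseline_rate <= 0:
            raise ValidationError("baseline_rate must be > 0")
        if not 0 < self.baseline_confluence <= 1:
            raise ValidationError("baseline_confluence must be in (0, 1]")


@dataclass(frozen=True)
class WellTimeSeries:
    """One well's wound-metric trajectory.

    ``wound_metric`` is the fraction of the initial wound area still open,
    in [0, 1], one value per timepoint; the first timepoint is the
    post-scratch baseline.  ``confluence`` is an optional overall cell-cover
    proxy used for toxicity flagging.
    """

    plate_id: str
    well: str
    cell_line: str
    compound_id: str
    dose: float
    replicate: int
    times: np.ndarray
    wound_metric: np.ndarray
    confluence: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        wound = np.asarray(self.wound_metric, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "wound_metric", wound)
        if self.confluence is not None:
            object.__setattr__(
                self, "confluence", np.asarray(self.confluence, dtype=float)
            )
        if times.size == 0:
            raise ValidationError(f"well {self.well}: empty time series")
        if times.size != wound.size:
            raise ValidationError(
                f"well {self.well}: times and wound_metric lengths differ"
            )
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"well {self.well}: times must be strictly increasing")
        if np.any(wound < 0) or np.any(wound > 1):
            raise ValidationError(
                f"well {self.well}: wound_metric must lie in [0, 1]"
            )


@dataclass(frozen=True)
class RosReading:
    """One well's endpoint DCF fluorescence (arbitrary units, >= 0)."""

    plate_id: str
    well: str
    cell_line: str
    compound_id: str
    dose: float
    replicate: int
    fluorescence: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.fluorescence) or self.fluorescence < 0:
            raise ValidationError(
                f"well {self.well}: fluorescence must be finite and >= 0"
            )


@dataclass
class EffectEstimate:
    """Vehicle-normalised effects for one (compound, cell line, dose).

    ``delta_migration`` is mean treated closure minus mean vehicle closure
    at the endpoint (a signed fraction); ``delta_ros`` is the relative
    change in mean fluorescence, (F_treated - F_vehicle) / F_vehicle.
    """

    compound_id: str
    cell_line: str
    dose: float
    delta_migration: float
    delta_ros: float
    n_replicates: int
    sd_migration: float = float("nan")
    sd_ros: float = float("nan")
    p_migration: Optional[float] = None
    p_ros: Optional[float] = None
    toxic: bool = False


@dataclass
class ScoreCard:
    """A compound's confirmation-screen scorecard.

    Four 0/1 matrices over (cell line x dose): directional calls for
    migration and ROS, and dose-response consistency calls for each assay.
    Subscores are the matrix sums (max 16 each; the two dose-response
    matrices together max 32); ``total`` (max 64) is their sum and drives a
    dense ranking in which tied totals share a rank label.
    """

    compound_id: str
    common_name: str = ""
    other_name: str = ""
    migration_matrix: Optional[pd.DataFrame] = None
    ros_matrix: Optional[pd.DataFrame] = None
    doseresp_migration_matrix: Optional[pd.DataFrame] = None
    doseresp_ros_matrix: Optional[pd.DataFrame] = None
    migration_subscore: int = 0
    ros_subscore: int = 0
    doseresp_subscore: int = 0
    rank: Optional[int] = None

    @property
    def total(self) -> int:
        return self.migration_subscore + self.ros_subscore + self.doseresp_subscore

    def validate(self) -> None:
        if not 0 <= self.migration_subscore <= 16:
            raise ValidationError(f"{self.compound_id}: migration subscore out of [0, 16]")
        if not 0 <= self.ros_subscore <= 16:
            raise ValidationError(f"{self.compound_id}: ROS subscore out of [0, 16]")
        if not 0 <= self.doseresp_subscore <= 32:
            raise ValidationError(f"{self.compound_id}: dose-response subscore out of [0, 32]")
        for name, mat, expected in (
            ("migration", self.migration_matrix, self.migration_subscore),
            ("ros", self.ros_matrix, self.ros_subscore),
        ):
            if mat is not None and int(mat.to_numpy().sum()) != expected:
                raise ValidationError(
                    f"{self.compound_id}: {name} subscore does not match its matrix"
                )
        if self.doseresp_migration_matrix is not None and self.doseresp_ros_matrix is not None:
            s = int(self.doseresp_migration_matrix.to_numpy().sum()) + int(
                self.doseresp_ros_matrix.to_numpy().sum()
            )
            if s != self.doseresp_subscore:
                raise ValidationError(
                    f"{self.compound_id}: dose-response subscore does not match matrices"
                )


@dataclass(frozen=True)
class AnimalModel:
    """Mouse parameters used for drinking-water dose translation.

    ``metabolic_factor`` converts a human per-kg daily dose into a mouse
    per-kg daily dose, compensating for the faster murine metabolism.
    """

    body_weight: float = 0.025  # kg; 25 g male, 18 g female
    water_intake: float = 10.0  # ml/day
    metabolic_factor: float = 12.3

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValidationError("body_weight must be > 0")
        if self.water_intake <= 0:
            raise ValidationError("water_intake must be > 0")
        if self.metabolic_factor <= 0:
            raise ValidationError("metabolic_factor must be > 0")


MALE_MOUSE = AnimalModel(body_weight=0.025)
FEMALE_MOUSE = AnimalModel(body_weight=0.018)


@dataclass(frozen=True)
class MouseDoseSpec:
    """A compound's dosing plan for one route and multiplier.

    Chow route: ``base_level`` is the mg of compound per kg of standard chow
    (the murine RDA content) and ``chow_concentration`` = base x multiplier.
    Water route: ``base_level`` is the mouse daily dose in mg/kg-body/day;
    ``daily_dose`` is the multiplied (and rounded) daily dose and
    ``water_concentration`` the resulting drinking-water strength in mg/ml.
    """

    compound_id: str
    route: str  # "chow" | "water"
    base_level: float
    multiplier: float
    chow_concentration: Optional[float] = None
    daily_dose: Optional[float] = None
    water_concentration: Optional[float] = None
    body_weight: Optional[float] = None
    rounding: str = "none"

    def __post_init__(self) -> None:
        if self.route not in ("chow", "water"):
            raise ValidationError(f"route must be 'chow' or 'water', got {self.route!r}")
        for name in ("base_level", "multiplier"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class ScreenDataset:
    """A full screen: manifest, wound time-series, ROS readings, and (for
    simulated screens) the planted ground truth.

    ``timeseries`` is long-format with one row per (well, timepoint) and
    columns ``plate_id, well, screen, cell_line, compound_id, dose_um,
    replicate, time_h, wound_metric, confluence``; ``ros`` has one row per
    well with ``fluorescence`` instead of the trajectory columns.
    """

    timeseries: pd.DataFrame
    ros: pd.DataFrame
    manifest: Optional[pd.DataFrame] = None
    truth: Optional[pd.DataFrame] = None
    config: Optional[SimConfig] = None

    def wells(self, **filters) -> list[WellTimeSeries]:
        """Materialise :class:`WellTimeSeries` records matching ``filters``
        (equality on any timeseries column, e.g. ``compound_id=...``)."""
        df = self.timeseries
        for col, val in filters.items():
            df = df[df[col] == val]
        out = []
        keys = ["plate_id", "well", "cell_line", "compound_id", "dose_um", "replicate"]
        for key, grp in df.groupby(keys, sort=True):
            grp = grp.sort_values("time_h")
            out.append(
                WellTimeSeries(
                    plate_id=key[0],
                    well=key[1],
                    cell_line=key[2],
                    compound_id=key[3],
                    dose=float(key[4]),
                    replicate=int(key[5]),
                    times=grp["time_h"].to_numpy(),
                    wound_metric=grp["wound_metric"].to_numpy(),
                    confluence=grp["confluence"].to_numpy()
                    if "confluence" in grp
                    else None,
                )
            )
        return out

    def ros_readings(self, **filters) -> list[RosReading]:
        df = self.ros
        for col, val in filters.items():
            df = df[df[col] == val]
        return [
            RosReading(
                plate_id=r.plate_id,
                well=r.well,
                cell_line=r.cell_line,
                compound_id=r.compound_id,
                dose=float(r.dose_um),
                replicate=int(r.replicate),
                fluorescence=float(r.fluorescence),
            )
            for r in df.itertuples()
        ]
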