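"""Readers and writers for the pipeline's tabular artifacts.

All tables are comma-separated UTF-8 text with a header row, ``.`` as the
decimal separator and ``#`` lines as comments (plate readers and
wound-imaging instruments export a zoo of dialects; this package reads and
writes exactly one).  Doses are always micromolar: a ``dose_unit`` column,
if present, must say so — readers refuse to convert other units silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .types import ScreenDataset, SimConfig, ValidationError

__all__ = [
    "read_table",
    "write_table",
    "load_manifest",
    "packaged_manifest",
    "reference_scorecard",
    "read_dataset",
    "write_dataset",
    "PipelineConfig",
    "load_config",
    "save_config",
]

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["compound_id", "common_name", "other_name", "source", "catalog_no"]
TIMESERIES_COLUMNS = [
    "plate_id", "well", "screen", "cell_line", "compound_id",
    "dose_um", "replicate", "time_h", "wound_metric",
]
ROS_COLUMNS = [
    "plate_id", "well", "screen", "cell_line", "compound_id",
    "dose_um", "replicate", "fluorescence",
]

_ACCEPTED_DOSE_UNITS = {"um", "µm", "μm", "uM", "µM", "μM"}


def read_table(path, required: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read one delimited table, enforcing the package dialect."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file (expected a header row)")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing column(s) {missing}")
    if "dose_unit" in df.columns:
        bad = sorted(
            u for u in df["dose_unit"].astype(str).str.strip().unique()
            if u.lower() not in {x.lower() for x in _ACCEPTED_DOSE_UNITS}
        )
        if bad:
            raise ValidationError(
                f"{path}: dose_unit must be µM; refusing to convert {bad}"
            )
        df = df.drop(columns=["dose_unit"])
    return df


def write_table(df: pd.DataFrame, path, header_comment: str = "") -> None:
    """Write one table in the package dialect (optionally with a leading
    ``#`` comment block)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as f:
        for line in filter(None, header_comment.splitlines()):
            f.write(f"# {line}\n")
        df.to_csv(f, index=False)


def _validate_manifest(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{origin}: manifest missing column(s) {missing}")
    if df.empty:
        raise ValidationError(f"{origin}: manifest has no entries")
    dup = df["compound_id"][df["compound_id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{origin}: duplicate compound_id(s) {dup}")
    return df.fillna({"other_name": ""})


def load_manifest(path) -> pd.DataFrame:
    """Load and validate a compound-library manifest."""
    return _validate_manifest(read_table(Path(path)), str(path))


def packaged_manifest() -> pd.DataFrame:
    """The packaged 104-compound library manifest (84 library-plate entries
    plus 20 named bioactive redox compounds)."""
    with resources.files("redoxscreen.data").joinpath("library_manifest.csv").open(
        "r", encoding="utf-8"
    ) as f:
        return _validate_manifest(
            pd.read_csv(f, comment="#"), "packaged manifest"
        )


def reference_scorecard() -> pd.DataFrame:
    """The packaged reference scorecard: printed component scores, totals
    and rank labels of the 18 ranked compounds of the screen this pipeline
    models (one row, the GSH row, is carried with its internally
    inconsistent printed total)."""
    with resources.files("redoxscreen.data").joinpath("reference_scorecard.csv").open(
        "r", encoding="utf-8"
    ) as f:
        return pd.read_csv(f, comment="#")


def write_dataset(dataset: ScreenDataset, outdir) -> None:
    """Write a screen dataset as its component tables (plus ground truth
    when simulated)."""
    outdir = Path(outdir)
    write_table(dataset.timeseries, outdir / "timeseries.csv",
                "Wound-metric trajectories, one row per (well, timepoint)")
    write_table(dataset.ros, outdir / "ros.csv",
                "Endpoint DCF fluorescence, one row per well")
    if dataset.manifest is not None:
        write_table(dataset.manifest, outdir / "manifest.csv", "Compound library")
    if dataset.truth is not None:
        write_table(dataset.truth, outdir / "truth.csv",
                    "Simulator ground truth (planted compound activities)")


def read_dataset(indir) -> ScreenDataset:
    """Read a screen dataset written by :func:`write_dataset` (or shaped
    like one)."""
    indir = Path(indir)
    ts = read_table(indir / "timeseries.csv", TIMESERIES_COLUMNS)
    ros = read_table(indir / "ros.csv", ROS_COLUMNS)
    manifest = None
    if (indir / "manifest.csv").exists():
        manifest = load_manifest(indir / "manifest.csv")
    truth = None
    if (indir / "truth.csv").exists():
        truth = read_table(indir / "truth.csv", ["compound_id", "class_label"])
    return ScreenDataset(timeseries=ts, ros=ros, manifest=manifest, truth=truth)


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of one end-to-end pipeline run.

    ``epsilon`` is the minimum vehicle-normalised effect for a directional
    call (default: one replicate-noise SD of the wound metric);
    ``tolerance`` the slack in the monotone dose-response comparison.  The
    effective config is serialised next to every run's outputs.
    """

    simulate: bool = True
    input_dir: Optional[str] = None
    output_dir: str = "results"
    n_compounds: int = 104
    seed: int = 0
    noise_sd: float = 0.02
    endpoint_h: float = 24.0
    epsilon: float = 0.02
    tolerance: float = 0.01
    significance_gate: bool = False
    toxicity_threshold: float = 0.2
    agg: str = "mean"
    doses_screen1: tuple[float, ...] = (5.0, 50.0)
    doses_screen2: tuple[float, ...] = (1.0, 5.0, 25.0, 125.0)

    def __post_init__(self) -> None:
        for name in ("doses_screen1", "doses_screen2"):
            doses = list(getattr(self, name))
            if any(d <= 0 for d in doses) or any(
                b <= a for a, b in zip(doses, doses[1:])
            ):
                raise ValidationError(
                    f"{name} must be strictly positive and ascending, got {doses}"
                )
        if not self.simulate and not self.input_dir:
            raise ValidationError("input_dir is required when simulate is off")
        if self.agg not in ("mean", "median"):
            raise ValidationError(f"agg must be 'mean' or 'median', got {self.agg!r}")


_BOOL_FIELDS = {"simulate", "significance_gate"}
_LIST_FIELDS = {"doses_screen1", "doses_screen2"}
_INT_FIELDS = {"n_compounds", "seed"}
_STR_FIELDS = {"input_dir", "output_dir", "agg"}


def load_config(path, **overrides) -> PipelineConfig:
    """Read a flat ``key = value`` config file (``#`` comments allowed);
    keyword overrides win over file values."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in PipelineConfig.__dataclass_fields__:
            raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _BOOL_FIELDS:
            values[key] = val.lower() in ("1", "true", "yes", "on")
        elif key in _LIST_FIELDS:
            values[key] = tuple(float(x) for x in val.replace(",", " ").split())
        elif key in _INT_FIELDS:
            values[key] = int(val)
        elif key in _STR_FIELDS:
            values[key] = val or None
        else:
            values[key] = float(val)
    values.update(overrides)
    return PipelineConfig(**values)


def save_config(config: PipelineConfig, path) -> None:
    """Serialise the effective config as a flat key-value file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# effective pipeline configuration"]
    for name in config.__dataclass_fields__:
        val = getattr(config, name)
        if isinstance(val, tuple):
            val = ", ".join(f"{v:g}" for v in val)
        elif val is None:
            val = ""
        lines.append(f"{name} = {val}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
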