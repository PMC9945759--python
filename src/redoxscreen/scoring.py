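"""Hit selection, binary scorecards and dense ranking.

The screen runs in two stages.  The primary screen tests the whole library
at two doses in one cell line; compounds that raise migration above the
vehicle at *both* doses (and are not cytotoxic) go forward.  The
confirmation screen tests survivors at four doses in four cell lines and
scores each compound 0/1 per (cell line, dose) cell on three criteria:

* increased migration — max 16 points (4 lines x 4 doses);
* decreased ROS — max 16 points;
* dose-dependent effects on migration and on ROS — max 16 + 16 = 32 points.

The three subscores sum to a total (max 64) which drives a dense ranking:
tied totals share a rank label and the next distinct total takes the next
integer label.

The dose-response criterion awards a (cell line, dose) cell a point when
the directional call holds at that dose *and* the effect magnitude in the
scored direction has not shrunk from the next-lower dose (beyond a small
tolerance); the lowest dose scores on its directional call alone.  This
allocates exactly one point per (cell line, dose, assay), consistent with
the 16 + 16 budget.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import ScoreCard, ValidationError

__all__ = [
    "select_first_screen",
    "score_binary",
    "score_dose_response",
    "build_scorecard",
    "total_and_rank",
    "cards_to_table",
]

logger = logging.getLogger(__name__)

#: Minimum effect size for a directional call; one replicate-noise SD of
#: the wound metric under the default assay model.
DEFAULT_EPSILON = 0.02

#: Slack allowed in the monotone dose-response comparison.
DEFAULT_TOLERANCE = 0.01

#: Significance level of the optional rank-test gate.
SIGNIFICANCE_ALPHA = 0.05


def _signed(delta: pd.DataFrame | pd.Series | float, assay: str):
    """Effect magnitude in the scored direction: migration is scored for
    increases, ROS for decreases."""
    if assay == "migration":
        return delta
    if assay == "ros":
        return -delta
    raise ValidationError(f"assay must be 'migration' or 'ros', got {assay!r}")


def select_first_screen(
    effects: pd.DataFrame,
    doses: Sequence[float] = (5.0, 50.0),
    epsilon: float = DEFAULT_EPSILON,
    exclude_toxic: bool = True,
) -> list[str]:
    """Primary-screen hit list.

    A compound is selected when its migration delta exceeds ``epsilon`` at
    *both* screening doses and it is not flagged cytotoxic at either.
    Compounds missing a dose are excluded with a logged warning rather than
    an error.  ``effects`` is a quantified effects table (one row per
    compound x cell line x dose); rows at other doses are ignored.
    """
    doses = [float(d) for d in doses]
    if len(doses) != 2:
        raise ValidationError(f"primary screen uses exactly 2 doses, got {doses}")
    df = effects[effects["dose_um"].isin(doses)]
    selected = []
    for cid, grp in df.groupby("compound_id", sort=True):
        present = set(grp["dose_um"])
        if not set(doses) <= present:
            logger.warning(
                "compound %s: missing dose(s) %s in primary screen, excluded",
                cid,
                sorted(set(doses) - present),
            )
            continue
        sub = grp[grp["dose_um"].isin(doses)]
        if exclude_toxic and sub["toxic"].any():
            continue
        per_dose = sub.groupby("dose_um")["delta_migration"].mean()
        if (per_dose > epsilon).all():
            selected.append(cid)
    return selected


def score_binary(
    deltas: pd.DataFrame,
    assay: str,
    epsilon: float = DEFAULT_EPSILON,
    pvalues: Optional[pd.DataFrame] = None,
    alpha: float = SIGNIFICANCE_ALPHA,
) -> pd.DataFrame:
    """Directional 0/1 matrix over (cell line x dose) for one compound.

    ``deltas`` is a cell-line-indexed DataFrame with ascending dose columns.
    A cell scores 1 when the delta is beyond ``epsilon`` in the scored
    direction (migration up, ROS down).  Missing cells score 0 with a
    warning.  When ``pvalues`` is given, cells additionally require
    p < ``alpha`` (the optional significance gate).
    """
    signed = _signed(deltas, assay)
    missing = signed.isna()
    if missing.to_numpy().any():
        logger.warning(
            "%s grid has %d missing cell(s); they score 0",
            assay,
            int(missing.to_numpy().sum()),
        )
    mat = (signed > epsilon) & ~missing
    if pvalues is not None:
        mat &= pvalues.notna() & (pvalues < alpha)
    return mat.astype(int)


def score_dose_response(
    deltas: pd.DataFrame,
    assay: str,
    epsilon: float = DEFAULT_EPSILON,
    tolerance: float = DEFAULT_TOLERANCE,
    binary: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Dose-response-consistency 0/1 matrix over (cell line x dose).

    Within each cell line (doses ascending left to right), a dose's cell
    scores 1 iff the directional call holds there and the signed magnitude
    is at least the next-lower dose's magnitude minus ``tolerance``; the
    lowest dose scores on the directional call alone.  Missing cells, and
    cells whose next-lower neighbour is missing (growth cannot be
    demonstrated), conservatively score 0.  Pass ``binary`` to
    reuse an already-computed directional matrix (e.g. one with the
    significance gate applied).
    """
    cols = list(deltas.columns)
    if any(float(b) <= float(a) for a, b in zip(cols, cols[1:])):
        raise ValidationError(f"dose columns must be ascending, got {cols}")
    if binary is None:
        binary = score_binary(deltas, assay, epsilon)
    signed = _signed(deltas, assay)
    out = binary.copy()
    for i, dose in enumerate(cols[1:], start=1):
        lower = cols[i - 1]
        grew = signed[dose] >= signed[lower] - tolerance
        out[dose] = (binary[dose].astype(bool) & grew.fillna(False)).astype(int)
    return out


def build_scorecard(
    effects: pd.DataFrame,
    compound_id: str,
    cell_lines: Sequence[str],
    doses: Sequence[float],
    epsilon: float = DEFAULT_EPSILON,
    tolerance: float = DEFAULT_TOLERANCE,
    significance_gate: bool = False,
    alpha: float = SIGNIFICANCE_ALPHA,
    common_name: str = "",
    other_name: str = "",
) -> ScoreCard:
    """Assemble one compound's confirmation-screen scorecard from the
    quantified effects table."""
    doses = [float(d) for d in doses]
    sub = effects[effects["compound_id"] == compound_id]

    def grid(col: str) -> pd.DataFrame:
        piv = sub.pivot_table(
            index="cell_line", columns="dose_um", values=col, aggfunc="mean"
        )
        return piv.reindex(index=list(cell_lines), columns=doses)

    d_mig, d_ros = grid("delta_migration"), grid("delta_ros")
    p_mig = grid("p_migration") if significance_gate else None
    p_ros = grid("p_ros") if significance_gate else None

    mig = score_binary(d_mig, "migration", epsilon, p_mig, alpha)
    ros = score_binary(d_ros, "ros", epsilon, p_ros, alpha)
    dr_mig = score_dose_response(d_mig, "migration", epsilon, tolerance, binary=mig)
    dr_ros = score_dose_response(d_ros, "ros", epsilon, tolerance, binary=ros)

    card = ScoreCard(
        compound_id=compound_id,
        common_name=common_name or compound_id,
        other_name=other_name,
        migration_matrix=mig,
        ros_matrix=ros,
        doseresp_migration_matrix=dr_mig,
        doseresp_ros_matrix=dr_ros,
        migration_subscore=int(mig.to_numpy().sum()),
        ros_subscore=int(ros.to_numpy().sum()),
        doseresp_subscore=int(dr_mig.to_numpy().sum()) + int(dr_ros.to_numpy().sum()),
    )
    card.validate()
    return card


def total_and_rank(cards: Sequence[ScoreCard]) -> list[ScoreCard]:
    """Dense-rank scorecards by total, descending.

    Equal totals share a rank label; the next distinct total takes the next
    integer.  Within a rank, cards are ordered by migration subscore
    (descending) then compound name — a deterministic presentation order
    that does not affect the labels.  Input order never matters.
    """
    for c in cards:
        c.validate()
    ordered = sorted(
        cards,
        key=lambda c: (-c.total, -c.migration_subscore, c.common_name, c.compound_id),
    )
    rank, prev_total = 0, None
    for c in ordered:
        if c.total != prev_total:
            rank += 1
            prev_total = c.total
        c.rank = rank
    return ordered


def cards_to_table(cards: Sequence[ScoreCard]) -> pd.DataFrame:
    """Ranked scorecards as a table with one row per compound: rank, names,
    the three subscores and the total."""
    return pd.DataFrame(
        [
            {
                "rank": c.rank,
                "compound_id": c.compound_id,
                "common_name": c.common_name,
                "other_name": c.other_name,
                "migration_max16": c.migration_subscore,
                "ros_max16": c.ros_subscore,
                "dose_response_max32": c.doseresp_subscore,
                "total_max64": c.total,
            }
            for c in cards
        ]
    )
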