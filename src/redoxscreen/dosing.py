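"""Human-to-mouse antioxidant dose translation.

Two dosing routes are supported, matching how the in-vivo arm of an
antioxidant intervention is typically set up:

* **Chow route** — for nutrients already present in standard rodent chow
  (e.g. carotenoids in R34): the supplemented concentration is the chow's
  RDA content multiplied by the chosen factor (e.g. 5x and 50x).
* **Water route** — for nutrients absent from chow (e.g. vitamin C, which
  mice synthesise themselves): the human RDA is converted to a per-kg daily
  dose, scaled by a metabolic factor (default 12.3) to compensate for the
  faster mouse metabolism, multiplied, and converted to a drinking-water
  concentration from the daily water intake and body weight.

Worked chain for vitamin C: 90 mg/day / 70 kg = 1.286 mg/kg/day;
x 12.3 = 15.82 mg/kg/day; x {5, 50} and rounded up to the nearest 10 =
{80, 800} mg/kg/day; at 10 ml/day intake that is 0.2 mg/ml for a 25 g male
and 1.44 mg/ml for an 18 g female (low dose).
"""

from __future__ import annotations

import math
from typing import Sequence

from .types import AnimalModel, MouseDoseSpec, ValidationError

__all__ = [
    "human_rda_per_kg",
    "human_to_mouse_dose",
    "chow_dose",
    "round_daily_dose",
    "water_concentration",
    "chow_dosing_plan",
    "water_dosing_plan",
]

#: Named rounding rules for multiplied water-route daily doses.
ROUNDING_RULES = ("none", "ceil10")


def human_rda_per_kg(rda: float, body_mass: float) -> float:
    """Human RDA (mg/day) as a per-kg daily dose (mg/kg/day), to 3 decimals.

    E.g. 90 mg/day for a 70 kg adult is 1.286 mg/kg/day.
    """
    if body_mass <= 0:
        raise ValidationError(f"body_mass must be > 0, got {body_mass}")
    if rda < 0:
        raise ValidationError(f"rda must be >= 0, got {rda}")
    return round(rda / body_mass, 3)


def human_to_mouse_dose(per_kg: float, metabolic_factor: float = 12.3) -> float:
    """Scale a human per-kg daily dose to a mouse per-kg daily dose, to 2
    decimals.  The default factor 12.3 compensates for the faster mouse
    metabolism."""
    if metabolic_factor <= 0:
        raise ValidationError(f"metabolic_factor must be > 0, got {metabolic_factor}")
    return round(per_kg * metabolic_factor, 2)


def chow_dose(base: float, multiplier: float) -> float:
    """Supplemented chow concentration (mg/kg chow): RDA content x factor."""
    if base < 0 or multiplier < 0:
        raise ValidationError("base and multiplier must be >= 0")
    return base * multiplier


def round_daily_dose(dose: float, rule: str = "ceil10") -> float:
    """Apply a named rounding rule to a multiplied daily dose (mg/kg/day).

    ``ceil10`` rounds up to the next multiple of 10 (79.1 -> 80,
    791 -> 800); ``none`` leaves the dose unchanged.  Practical dosing
    levels are round numbers; the rule used is recorded in every plan.
    """
    if rule == "none":
        return dose
    if rule == "ceil10":
        return math.ceil(dose / 10.0) * 10.0
    raise ValidationError(f"unknown rounding rule {rule!r}; use one of {ROUNDING_RULES}")


def water_concentration(daily_dose: float, animal: AnimalModel) -> float:
    """Drinking-water concentration (mg/ml) delivering ``daily_dose``
    (mg/kg/day) to an animal of the model's body weight and water intake."""
    if daily_dose < 0:
        raise ValidationError(f"daily_dose must be >= 0, got {daily_dose}")
    return daily_dose * animal.body_weight / animal.water_intake


def chow_dosing_plan(
    compound_id: str,
    base: float,
    multipliers: Sequence[float] = (5.0, 50.0),
) -> list[MouseDoseSpec]:
    """Chow-route plan: one spec per multiplier."""
    return [
        MouseDoseSpec(
            compound_id=compound_id,
            route="chow",
            base_level=base,
            multiplier=m,
            chow_concentration=chow_dose(base, m),
        )
        for m in multipliers
    ]


def water_dosing_plan(
    compound_id: str,
    human_rda: float,
    human_mass: float = 70.0,
    multipliers: Sequence[float] = (5.0, 50.0),
    animal: AnimalModel = AnimalModel(),
    rounding: str = "ceil10",
) -> list[MouseDoseSpec]:
    """Water-route plan from the human RDA: one spec per multiplier.

    The chain is per-kg RDA -> metabolic scaling -> multiplication ->
    rounding rule -> water concentration for the given animal model.
    """
    per_kg = human_rda_per_kg(human_rda, human_mass)
    mouse_daily = human_to_mouse_dose(per_kg, animal.metabolic_factor)
    plan = []
    for m in multipliers:
        daily = round_daily_dose(mouse_daily * m, rounding)
        plan.append(
            MouseDoseSpec(
                compound_id=compound_id,
                route="water",
                base_level=mouse_daily,
                multiplier=m,
                daily_dose=daily,
                water_concentration=water_concentration(daily, animal),
                body_weight=animal.body_weight,
                rounding=rounding,
            )
        )
    return plan
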