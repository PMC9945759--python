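"""Translate human antioxidant RDAs into mouse dosing plans.

Water route (vitamin C, absent from rodent chow): human RDA -> per-kg dose
-> metabolic scaling (x12.3) -> 5x/50x multipliers, rounded up to the next
10 mg/kg/day -> drinking-water concentration.  Chow route (carotenoids):
the chow's RDA content times the multiplier.
"""

from redoxscreen import (
    FEMALE_MOUSE,
    MALE_MOUSE,
    chow_dosing_plan,
    human_rda_per_kg,
    human_to_mouse_dose,
    water_dosing_plan,
)

per_kg = human_rda_per_kg(90, 70)
mouse = human_to_mouse_dose(per_kg)
print(f"vitamin C: 90 mg/day / 70 kg = {per_kg} mg/kg/day; "
      f"x 12.3 = {mouse} mg/kg/day in the mouse")

for animal, label in [(MALE_MOUSE, "25 g male"), (FEMALE_MOUSE, "18 g female")]:
    for spec in water_dosing_plan("vitamin-c", 90, animal=animal):
        print(f"  {label}: x{spec.multiplier:g} -> {spec.daily_dose:g} mg/kg/day "
              f"-> {spec.water_concentration:.2f} mg/ml drinking water")

print("\nchow route (mg per kg chow = RDA content x multiplier):")
for cid, base in [("beta-carotene", 7.2), ("retinyl-palmitate", 6.6)]:
    plan = chow_dosing_plan(cid, base)
    doses = ", ".join(f"x{s.multiplier:g} -> {s.chow_concentration:g}" for s in plan)
    print(f"  {cid} (RDA {base} mg/kg chow): {doses}")
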