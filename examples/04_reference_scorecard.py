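"""Scorecard arithmetic on the shipped 18-compound reference ranking.

The package ships the printed component scores of the 18 ranked compounds
from the melanoma redox screen it models.  This example re-derives every
total and rank label from the components alone.
"""

from redoxscreen import ScoreCard, cards_to_table, reference_scorecard, total_and_rank

ref = reference_scorecard()
cards = [
    ScoreCard(compound_id=r.common_name, common_name=r.common_name,
              other_name=r.other_name,
              migration_subscore=int(r.migration_max16),
              ros_subscore=int(r.ros_max16),
              doseresp_subscore=int(r.total_max64 - r.migration_max16
                                    - r.ros_max16))
    for r in ref.itertuples()
]
table = cards_to_table(total_and_rank(cards))
print(table.drop(columns=["compound_id"]).to_string(index=False))
print(
    "\nVitamin C tops the list at 14 + 9 + 19 = 42 of 64; the two compounds "
    "totalling 40\nshare rank 3 and the next total (29) takes rank 4.  The "
    "GSH row's dose-response\ncomponent is back-computed from its printed "
    "total, which is known to disagree\nwith its printed components."
)
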