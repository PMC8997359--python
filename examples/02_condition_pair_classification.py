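"""Classify TAD borders between a wild-type and an edited knockdown.

Simulates a WT/knockdown pair at 500-bp bins where some planted borders are
deleted, some are shifted by 1.5 kb (within the 2-kb "fuzzy" tolerance),
and some are shifted 10 kb (scored lost + new). The classifier's statuses
are compared with the scripted intent.
"""
import numpy as np

from tadremodel import (
    BorderEdit,
    PlantedBorder,
    SyntheticSpec,
    balance,
    call_borders,
    classify_borders,
    insulation_score,
    simulate_condition_pair,
)
from tadremodel.tad_analysis import status_counts

res = 500
positions = (np.linspace(80_000, 1_920_000, 12) // res * res).astype(int)
spec = SyntheticSpec(
    genome={"chr2L": 2_000_000}, resolution=res,
    borders=[PlantedBorder("chr2L", int(p), 3.0) for p in positions],
    depth=5_000_000, seed=4)

edits = [BorderEdit("chr2L", int(positions[0]), "delete"),
         BorderEdit("chr2L", int(positions[3]), "delete"),
         BorderEdit("chr2L", int(positions[6]), "shift", delta=1500),
         BorderEdit("chr2L", int(positions[9]), "shift", delta=10_000)]
wt_m, kd_m, wt_truth, _ = simulate_condition_pair(spec, edits,
                                                  same_tol=res)


def call(m):
    b = balance(m)
    return call_borders(insulation_score(b), b)


wt_borders = [b for b in call(wt_m) if b.strength == "strong"]
kd_borders = call(kd_m)
comps = classify_borders(wt_borders, kd_borders, fuzzy_tol=2000,
                         same_tol=res)
print("intended:", wt_truth.borders["status"].value_counts().to_dict())
print("called:  ", status_counts(comps))
# maintained = same position and strength; fuzzy = moved <= 2 kb;
# lost = no knockdown border nearby; new = knockdown-only strong border.
for c in comps:
    if c.status != "maintained":
        pos = (c.wt_border or c.kd_border).midpoint
        shift = f", shift {c.shift} bp" if c.shift else ""
        print(f"  {c.status:<10} near {pos:>9,}{shift}")
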