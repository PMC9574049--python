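"""Distance summaries of the bundled published per-subject tables.

The package ships the per-subject intra-scanner (V1 vs V2) peak-distance
tables of a published 21-subject test-retest study, one per total-component
setting. Feeding them through the summary operations reproduces the
printed Mean/STD rows and the fraction of peaks within 0-10 mm.
"""

from smnpeak import (DISTANCE_CELLS, load_reference_distances,
                     proportion_within, summarize_distances)
from smnpeak.reliability import DistanceTable

for setting in (20, 30, 40):
    table = load_reference_distances(setting)
    print(f"\n{setting} components:")
    for cell in DISTANCE_CELLS:
        mean, std, n = summarize_distances(
            dict(zip(table["subject"], table[cell])))
        print(f"  {cell:>9}: mean {mean:6.2f} mm, SD {std:6.2f} mm (n={n})")

ref40 = load_reference_distances(40)
tables = [
    DistanceTable(condition=c.split("_")[0], side=c.split("_")[1],
                  visit_pair=("V1", "V2"), n_components=40,
                  distances=dict(zip(ref40["subject"], ref40[c])),
                  mean_mm=0.0, std_mm=0.0, n_used=int(ref40[c].notna().sum()))
    for c in DISTANCE_CELLS
]
frac = proportion_within(tables, 0.0, 10.0)
print(f"\n40-component peaks within 0-10 mm across sessions: {frac:.0%}")
# Even at the most reliable setting, most subjects' peaks move by more than
# 10 mm between visits -- the motivation for quantifying reliability before
# using the peak as an individual stimulation target.
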