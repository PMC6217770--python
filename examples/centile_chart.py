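"""Build the five-centile chart table (the printable deliverable).

P2.3/P16/P50/P84/P97.7 correspond to -2/-1/0/+1/+2 SD on the
normal-equivalent z scale; the table below is the normal-weight analogue of
a published week-by-week chart.
"""

from gwgcharts import BMIGroup, SyntheticConfig, simulate_cohort
from gwgcharts.charts import build_centile_table, export_parameter_grid
from gwgcharts.pipeline import fit_group_chart

cohort = simulate_cohort(
    SyntheticConfig(n_women=5000, seed=11), groups=[BMIGroup.NORMAL]
)
chart = fit_group_chart(cohort, BMIGroup.NORMAL, nudge_seed=11)
table = build_centile_table(export_parameter_grid(chart))

print("week   P2.3    P16    P50    P84  P97.7   (gain, kg)")
for week, vals in table.rows:
    if week % 4 == 0:
        print(f"{week:4d} " + " ".join(f"{v:6.2f}" for v in vals))
print("\nCentiles never cross (a property the distributional fit "
      "guarantees, unlike independently-estimated quantile curves).")
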