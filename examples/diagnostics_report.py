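"""Model-adequacy diagnostics for a fitted chart.

Worm-plot flatness, Q statistics per residual moment, centile coverage and
the BIC margin over a straight-line model — the same evidence used to pick
smoothing settings.
"""

from gwgcharts import BMIGroup, SyntheticConfig, simulate_cohort
from gwgcharts.charts import export_parameter_grid
from gwgcharts.diagnostics import (
    centile_coverage,
    chart_residuals,
    compare_bic,
    q_statistics,
    worm_plot_data,
)
from gwgcharts.pipeline import fit_group_chart, prepare_group
from gwgcharts.smooth_fit import fit_linear_baseline

import numpy as np

cohort = simulate_cohort(
    SyntheticConfig(n_women=5000, seed=11), groups=[BMIGroup.NORMAL]
)
chart = fit_group_chart(cohort, BMIGroup.NORMAL, nudge_seed=11)
data = prepare_group(cohort, BMIGroup.NORMAL, nudge_seed=11)
grid = export_parameter_grid(chart)
z, ga = chart_residuals(data, grid)

print("worm plot (4 age bins): fraction of points inside the 95% band")
for b in worm_plot_data(z, ga, n_bins=4):
    frac = np.mean(np.abs(b.deviation) <= b.band)
    print(f"  GA {b.ga_range[0]:5.1f}-{b.ga_range[1]:5.1f} wk  n={b.n:5d}  "
          f"{100 * frac:5.1f}% in band")

print("\nQ statistics (8 age groups):")
for moment, q in q_statistics(z, ga, n_groups=8, fitted_df={
        "mu": 8.0, "sigma": 3.0, "nu": 2.0, "tau": 2.0}).items():
    print(f"  {moment:9s} Q={q.statistic:7.2f} df={q.df:.0f} p={q.p_value:.3f}")

cover = centile_coverage(data, grid)
print("\ncentile coverage (empirical fraction below each curve):")
print("  " + "  ".join(f"P{k:g}: {v:.3f}" for k, v in sorted(cover.items())))

delta = compare_bic(chart, fit_linear_baseline(data))
print(f"\ndelta BIC (linear - chart): {delta:+.0f}  "
      "(positive = the smooth distributional chart is the better model)")
print("\nReading: coverage and the mid/late worms are clean, while the "
      "early-pregnancy worm and the mean/variance Q statistics flag "
      "residual local misfit — measurement error dominates the small "
      "early gains, and the default smoothing is too stiff to absorb it. "
      "That is the trade-off the diagnostics exist to expose; raising the "
      "S-curve df in the ModelSpec softens it.")
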