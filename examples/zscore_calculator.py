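"""Score an individual gain against a fitted chart.

A woman with pre-pregnancy BMI 22 (normal weight) has gained 10.0 kg by
30 weeks + 4 days (30.57 weeks).  Where does she sit on the chart?
"""

from gwgcharts import BMIGroup, SyntheticConfig, simulate_cohort
from gwgcharts.charts import export_parameter_grid, gain_to_zscore, zscore_to_gain
from gwgcharts.pipeline import fit_group_chart

cohort = simulate_cohort(
    SyntheticConfig(n_women=5000, seed=11), groups=[BMIGroup.NORMAL]
)
chart = fit_group_chart(cohort, BMIGroup.NORMAL, nudge_seed=11)
grid = export_parameter_grid(chart)  # week-indexed (mu, sigma, nu, tau)

res = gain_to_zscore(10.0, 30.57, BMIGroup.NORMAL, grid)
print(f"gain 10.0 kg at 30.57 weeks, normal-weight chart:")
print(f"  z (t scale)        {res['z_raw']:+.3f}")
print(f"  z (normal scale)   {res['z_normal']:+.3f}")
print(f"  percentile         {res['percentile']:.1f}")

band = {z: zscore_to_gain(float(z), 30.57, BMIGroup.NORMAL, grid)
        for z in (-2, 0, 2)}
print(f"\nchart band at 30.57 weeks: P2.3 = {band[-2]:.1f} kg, "
      f"P50 = {band[0]:.1f} kg, P97.7 = {band[2]:.1f} kg")
print("A z of +1 means she has gained more than ~84% of women of her "
      "BMI group at the same gestational age.")
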