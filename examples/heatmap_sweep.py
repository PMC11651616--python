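"""Sweep the maintenance-cost ratios (beta, delta) and map the optimal
active fraction.

High delta (expensive maintenance) and low beta (cheap idleness) favour
leaving weak workers inactive; the beta=1 row and delta=0 column always
favour full activity because idling saves nothing there.
"""

from idlecolony import DistributionSpec, SweepConfig, run_sweep, write_heatmap_csv

config = SweepConfig(
    distribution=DistributionSpec(kind="right_skew"),
    n_workers=500,
    n_replicates=200,
    base_seed=0,
)
result = run_sweep(config)
grid = result.grid

print(f"grid cells: {len(grid)} (19 beta x 101 delta)")
print(f"cells favouring some inactivity: {(grid['optimal_active_fraction'] < 1).sum()}")
print(f"smallest optimal active fraction: {grid['optimal_active_fraction'].min():.2f}")
for beta, delta in [(0.1, 8.0), (0.2, 2.0), (0.6, 2.0), (1.0, 5.0)]:
    row = grid[(grid.beta == beta) & (grid.delta == delta)].iloc[0]
    print(f"  beta={beta:.2f} delta={delta:.1f} -> optimal fraction {row.optimal_active_fraction:.2f}")

write_heatmap_csv(result, "heatmap_right_skew_N500.csv")
print(
    "\nWrote heatmap_right_skew_N500.csv; each row gives, for one (beta,"
    "\ndelta) pair, the active fraction that maximizes mean colony efficiency."
)
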