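"""How the optimal active fraction depends on colony size and on the
efficiency definition.

Colony size barely moves the optimum (50 vs 500 workers). The efficiency
definition does: with performance/cost (ratio mode) the optimum is
interior, while performance-minus-cost (difference mode) at production
cost 100 is dominated by costs - every extra activation costs
delta*100*(1-beta) units but yields at most 1 - so it always favours the
minimum activity on the grid.
"""

from idlecolony import (
    DistributionSpec,
    EfficiencyMode,
    SweepConfig,
    aggregate_curve,
    optimal_active_fraction,
    run_replicates,
)


def optimum(kind, n, mode, replicates):
    config = SweepConfig(
        distribution=DistributionSpec(kind=kind),
        n_workers=n,
        n_replicates=replicates,
        mode=mode,
        base_seed=0,
    )
    curve = aggregate_curve(run_replicates(config), beta=0.2, delta=2.0, config=config)
    return optimal_active_fraction(curve)


print(f"{'distribution':12s} {'N=50':>6s} {'N=500':>6s} {'N=500 diff-mode':>16s}")
for kind in ("normal", "bimodal", "uniform", "left_skew", "right_skew"):
    n50 = optimum(kind, 50, EfficiencyMode.RATIO, 1000)
    n500 = optimum(kind, 500, EfficiencyMode.RATIO, 1000)
    diff = optimum(kind, 500, EfficiencyMode.DIFFERENCE, 1000)
    print(f"{kind:12s} {n50:6.2f} {n500:6.2f} {diff:16.2f}")
print(
    "\nRatio-mode optima agree across colony sizes to within one coarse grid"
    "\nstep; difference-mode optima collapse to the smallest active count"
    "\n(fraction 0.02) because costs exceed performance at this cost scale."
)
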