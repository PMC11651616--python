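# Methods

## The model

A colony of *N* interchangeable workers (no castes, no body-size
polymorphism) pays two kinds of cost over a period equal to one worker
lifetime: a one-off **production cost** *c_p* per worker (default 100
arbitrary units) and a **maintenance cost** expressed through two
dimensionless ratios. δ ≥ 0 is the ratio of an active worker's lifetime
maintenance cost to its production cost (δ > 1 means a worker costs more
to keep than to make). β ∈ [0, 1] is the ratio of an inactive worker's
maintenance cost to an active worker's (β → 0: idle workers are almost
free; β = 1: activity state is irrelevant to cost). With *k* of *N*
workers active,

    Cost(k) = c_p·N + δ·c_p·(k + β·(N − k)).

Each worker's **individual performance** — its effectiveness at task
completion, or equivalently its sensitivity to task stimuli — is a single
random draw on [0, 1], fixed for life (no maturation or aging). Only
active workers contribute; the colony activates the *k* best performers,
so colony performance is the sum of the *k* largest draws, computed for a
whole *k*-grid at once via one descending sort and prefix sums.

**Efficiency** is Performance/Cost (ratio mode, the default) or
Performance − Cost (difference mode). Curves over *k* are normalized by
the all-active value, so the curve equals 1 at *k* = *N* and values above
1 quantify the benefit of partial activity. Normalization by a positive
constant never moves the argmax, so optima are unaffected by it in ratio
mode.

## Performance distributions

Five families, all with support [0, 1]:

| kind        | construction                                   | mean | SD    |
|-------------|------------------------------------------------|------|-------|
| normal      | N(0.5, 0.2) truncated by rejection             | 0.5  | 0.191 |
| uniform     | U(0, 1)                                        | 0.5  | 0.289 |
| bimodal     | ½N(0.1, 0.2) + ½N(0.9, 0.2), truncated by clip | 0.5  | 0.390 |
| left_skew   | u^(1/4), u ~ U(0, 1)                           | 0.8  | 0.163 |
| right_skew  | 1 − u^(1/4)                                    | 0.2  | 0.163 |

Two truncation policies are exposed because they are genuinely different
distributions: **rejection** (resample until in range) renormalizes the
density and shrinks the spread, while **clip** (clamp to the bounds)
piles tail mass into atoms at 0 and 1 and widens it. The defaults —
rejection for the normal, clip for the bimodal — are the unique pairing
that yields the calibrated spreads above (rounding to 0.19 and 0.39; a
clipped normal would give 0.198 and a rejected bimodal 0.329). Both were
re-verified against the package's `analytic_moments` oracle, which uses
closed forms where they exist (uniform, power-transformed skews,
rejection-truncated normal via standard truncated-normal moments) and
numeric integration of the parent density plus boundary atoms for the
clipped cases. The bimodal mixture weight defaults to ½/½, forced by the
requirement that the family be symmetric with mean 0.5.

## Simulation protocol and reproducibility

The reference protocol is: colony sizes 50, 500 or 5000; active counts
from 10 to *N* in steps of 5 (with *N* appended if the stride misses it);
β from 0.1 to 1 in steps of 0.05; δ from 0 to 10 in steps of 0.1; 1000
replicates per condition (100 for *N* = 5000, whose curves are already
very tight). Every replicate draws a fresh colony; replicate *r* consumes
the independent substream seeded by `(base_seed, r)`, so results are
bit-reproducible and independent of evaluation order.

By default the **same replicate set is reused across all (β, δ) cells**
(common random numbers): the cost side of efficiency is deterministic, so
sharing samples makes neighbouring heat-map cells differ only through the
cost parameters, not through sampling noise, and makes cross-cell
comparisons paired. A config switch (`common_random_numbers: false`)
draws fresh samples per cell for fully independent runs.

Aggregation: per-replicate normalized curves are averaged pointwise and a
**single argmax is taken on the mean curve** (the readout a single
mean-curve figure implies). The per-replicate argmax distribution is
recorded on each `EfficiencyCurve` as a diagnostic; for nearly flat
curves it scatters widely even when the mean-curve optimum is stable.
Exact ties in the argmax are broken **toward the largest k**: when
idling saves nothing, the colony should not idle anyone. Ties among equal
performances at the k-th rank are broken by worker index (stable sort);
the selected sum is unaffected. In ratio mode with common random numbers
the cell loop uses the exact factorization
mean[(P_k/C_k)/(P_N/C_N)] = mean[P_k/P_N]·C_N/C_k, computing the
sample-dependent factor once per sweep.

*k* = 0 is excluded (zero performance, and the reference grids start at
10 actives). Difference-mode normalization divides by the all-active
difference only when that reference is positive; otherwise the raw
difference curve is returned with a `normalized=False` flag and the
argmax is taken on the raw curve (dividing by a negative reference would
invert the ordering).

## Behaviour at the reference settings

At δ = 2, β = 0.2, *N* = 500, 1000 replicates, ratio mode, the optimal
active fractions are: left_skew 0.97, normal 0.88, uniform 0.71,
right_skew 0.60, bimodal 0.57. Three properties of these numbers are
worth recording:

- **Variance widens the inactivity region.** Across the full (β, δ) grid
  the number of cells favouring some inactivity grows with the spread of
  the symmetric families: normal 1564 < uniform 1796 ≤ bimodal 1800 of
  1919 cells.
- **The clipped bimodal slightly undercuts the right skew at this single
  point** (0.57 vs 0.60), because its atom of perfect performers makes
  the marginal active worker drop off sharply past the upper mode. Over
  the whole grid the right skew still reaches the lowest optima of any
  family (minimum 0.34 vs 0.47 for the bimodal), so "right skew tolerates
  the most inactivity" holds map-wide but not cell-by-cell.
- **The left-skew curve is nearly flat near full activity**: its interior
  optimum at 0.96–0.97 exceeds the all-active value by under 0.4%, which
  is why such colonies are well described as keeping everyone active even
  though the literal argmax is a few grid steps below 1.

**Difference mode is cost-dominated at this cost scale.** With *c_p* =
100 and individual performances ≤ 1, activating one more worker costs
δ·c_p·(1 − β) (160 units at the illustration point) and yields at most 1,
so the raw difference curve is strictly decreasing and its argmax is the
smallest grid count (fraction 0.02) whenever δ > 0 and β < 1. Ratio and
difference modes therefore agree only where cost is activity-independent
(δ = 0 or β = 1) or when performance is rescaled to the cost scale; the
package reports the difference-mode result faithfully rather than
adjusting either scale.

## What the generator does and does not emulate

The synthetic colonies capture randomness in worker quality and nothing
else: no task structure, no spatial interactions, no worker turnover,
learning or senescence, and no feedback from colony state to individual
performance. Passing tests therefore show that the cost–benefit logic and
its implementation are correct under pure sampling variation; they say
nothing about how real colonies allocate work, where performance is
neither static nor exogenous.

## Numerical choices and problem sizes

- Rejection sampling is vectorized and refills only the out-of-range
  remainder; for every admissible parameter set the acceptance mass is
  far from zero.
- Curves use float64 throughout; the normalization reference at *k* = *N*
  is exact (a value divided by itself), so the curve-equals-1 invariant
  holds to full precision.
- Default test and acceptance runs use *N* = 500 with 100 replicates for
  exact degenerate-row checks and 1000 replicates for the stochastic
  cross-distribution comparisons; with common random numbers and the
  ratio-mode factorization a full 1919-cell sweep at 1000 replicates
  takes on the order of a second.
- Heat-map CSVs are written beta-major (β, then δ, then *k*) with
  shortest-round-trip float formatting; reading them back with the
  package's readers reproduces the in-memory values bit-exactly.

## Known limitations

- The optimal fraction is resolved only to the *k*-grid stride (5
  workers, i.e. 0.01 in fraction at *N* = 500, 0.1 at *N* = 50).
- For nearly flat efficiency curves (low δ, high β, or left-skewed
  performance) the argmax is poorly conditioned: tiny efficiency
  differences decide between distant fractions. The recorded
  per-replicate argmax dispersion flags these cases.
- Difference-mode results depend on the arbitrary cost scale (see above),
  unlike ratio-mode results, which are invariant to it.
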