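"""Replicated parameter sweeps over (beta, delta) and optimal active
fractions.

A sweep draws ``n_replicates`` independent colonies from one performance
distribution, computes a normalized efficiency curve over the active-count
grid for every (beta, delta) pair, averages the curves pointwise over
replicates, and reads off the active fraction maximizing the mean curve.
By default the same replicate samples are reused across all grid cells
(common random numbers), so differences between cells reflect the cost
parameters rather than sampling noise.

Each replicate consumes an independent substream seeded from
``(base_seed, replicate_index)``, making sweeps reproducible and
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .colony import CostParameters, EfficiencyMode, cost_for_active_counts, topk_prefix_sums
from .distributions import DistributionSpec, PerformanceSample, sample_performances

__all__ = [
    "SweepConfig",
    "EfficiencyCurve",
    "SweepResult",
    "default_beta_grid",
    "default_delta_grid",
    "default_k_grid",
    "run_replicates",
    "aggregate_curve",
    "optimal_active_fraction",
    "run_sweep",
]


def default_beta_grid() -> np.ndarray:
    """beta from 0.1 to 1 in steps of 0.05."""
    return np.round(np.arange(0.1, 1.0 + 1e-9, 0.05), 10)


def default_delta_grid() -> np.ndarray:
    """delta from 0 to 10 in steps of 0.1."""
    return np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)


def default_k_grid(n_workers: int, stride: int = 5) -> np.ndarray:
    """Active counts from 10 up to ``n_workers`` in steps of ``stride``.

    ``n_workers`` is appended when the stride does not land on it, since the
    all-active point is the normalization reference.
    """
    if n_workers < 10:
        return np.arange(1, n_workers + 1)
    grid = np.arange(10, n_workers + 1, stride)
    if grid[-1] != n_workers:
        grid = np.append(grid, n_workers)
    return grid


@dataclass(frozen=True, eq=False)
class SweepConfig:
    """Full specification of one replicated (beta, delta) sweep."""

    distribution: DistributionSpec
    n_workers: int
    beta_grid: np.ndarray = None
    delta_grid: np.ndarray = None
    k_grid: np.ndarray = None
    n_replicates: int = 1000
    mode: EfficiencyMode = EfficiencyMode.RATIO
    base_seed: int = 0
    production_cost: float = 100.0
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError(f"n_workers must be >= 1, got {self.n_workers}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if not 0 <= int(self.base_seed) < 2**63:
            raise ValueError(f"base_seed must be a non-negative integer, got {self.base_seed}")
        if not self.production_cost > 0:
            raise ValueError(f"production_cost must be > 0, got {self.production_cost}")
        object.__setattr__(self, "mode", EfficiencyMode(self.mode))

        beta = default_beta_grid() if self.beta_grid is None else np.asarray(self.beta_grid, dtype=float)
        delta = default_delta_grid() if self.delta_grid is None else np.asarray(self.delta_grid, dtype=float)
        if beta.size == 0 or np.any(np.diff(beta) <= 0):
            raise ValueError("beta_grid must be non-empty and strictly increasing")
        if beta[0] < 0 or beta[-1] > 1:
            raise ValueError("beta_grid values must lie in [0, 1]")
        if delta.size == 0 or np.any(np.diff(delta) <= 0):
            raise ValueError("delta_grid must be non-empty and strictly increasing")
        if delta[0] < 0:
            raise ValueError("delta_grid values must be >= 0")

        k = default_k_grid(self.n_workers) if self.k_grid is None else np.asarray(self.k_grid, dtype=int)
        if k.size == 0 or np.any(np.diff(k) <= 0):
            raise ValueError("k_grid must be non-empty and strictly increasing")
        if k[0] < 1 or k[-1] > self.n_workers:
            raise ValueError(f"k_grid must lie within [1, {self.n_workers}]")
        if k[-1] != self.n_workers:
            raise ValueError(f"k_grid must contain n_workers={self.n_workers}")

        object.__setattr__(self, "beta_grid", beta)
        object.__setattr__(self, "delta_grid", delta)
        object.__setattr__(self, "k_grid", k)


@dataclass(frozen=True, eq=False)
class EfficiencyCurve:
    """Replicate-averaged normalized efficiency over the active-count grid.

    ``dispersion`` is the across-replicate standard deviation at each grid
    point; ``replicate_argmax_fractions`` records the per-replicate argmax
    positions (a diagnostic for how sharply the optimum is determined).
    ``normalized`` is False only in difference mode when the all-active
    reference was non-positive, in which case ``mean_normalized_efficiency``
    holds the raw mean difference curve.
    """

    k_values: np.ndarray
    active_fractions: np.ndarray
    mean_normalized_efficiency: np.ndarray
    dispersion: np.ndarray
    normalized: bool
    beta: float
    delta: float
    mode: EfficiencyMode
    distribution: DistributionSpec
    n_workers: int
    n_replicates: int
    replicate_argmax_fractions: np.ndarray | None = field(default=None, compare=False)


@dataclass(frozen=True, eq=False)
class SweepResult:
    """Optimal active fraction and efficiency at the optimum for every
    (beta, delta) cell, as a tidy DataFrame ``grid`` with columns ``beta``,
    ``delta``, ``optimal_active_fraction``, ``efficiency_at_optimum``."""

    grid: pd.DataFrame
    config: SweepConfig


def _replicate_rng(base_seed: int, replicate: int, cell: int | None = None) -> np.random.Generator:
    key = [int(base_seed), int(replicate)]
    if cell is not None:
        key.insert(1, int(cell))
    return np.random.default_rng(key)


def run_replicates(config: SweepConfig, cell: int | None = None) -> list[PerformanceSample]:
    """Draw the replicate performance samples for a sweep.

    Replicate ``r`` uses the substream seeded by ``(base_seed, r)`` (or
    ``(base_seed, cell, r)`` when per-cell samples are requested), so the
    collection is reproducible bit-for-bit and independent of evaluation
    order.
    """
    return [
        sample_performances(
            config.distribution,
            config.n_workers,
            _replicate_rng(config.base_seed, r, cell),
        )
        for r in range(config.n_replicates)
    ]


def _prefix_matrix(samples: Sequence[PerformanceSample], k_grid: np.ndarray) -> np.ndarray:
    """(replicates, len(k_grid)) matrix of top-k performance sums."""
    out = np.empty((len(samples), len(k_grid)))
    for i, s in enumerate(samples):
        out[i] = topk_prefix_sums(s.values)[k_grid - 1]
    return out


def _curves_matrix(
    perf: np.ndarray, cost: np.ndarray, mode: EfficiencyMode
) -> tuple[np.ndarray, bool]:
    """Per-replicate normalized curves; falls back to raw difference curves
    (normalized=False) when any all-active reference is non-positive."""
    if mode is EfficiencyMode.RATIO:
        eff = perf / cost
        return eff / eff[:, -1:], True
    eff = perf - cost
    ref = eff[:, -1]
    if np.all(ref > 0):
        return eff / ref[:, None], True
    return eff, False


def aggregate_curve(
    samples: Sequence[PerformanceSample],
    beta: float,
    delta: float,
    config: SweepConfig,
) -> EfficiencyCurve:
    """Average per-replicate normalized efficiency curves at one
    (beta, delta)."""
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    params = CostParameters(delta=delta, beta=beta, production_cost=config.production_cost)
    k_grid = config.k_grid
    perf = _prefix_matrix(samples, k_grid)
    cost = np.asarray(cost_for_active_counts(params, config.n_workers, k_grid))
    curves, normalized = _curves_matrix(perf, cost, config.mode)

    mean = curves.mean(axis=0)
    if curves.shape[0] > 1:
        disp = curves.std(axis=0, ddof=1)
    else:
        disp = np.zeros_like(mean)
    # per-replicate argmax, ties toward the largest k
    rev = curves[:, ::-1]
    arg = curves.shape[1] - 1 - np.argmax(rev, axis=1)
    return EfficiencyCurve(
        k_values=k_grid,
        active_fractions=k_grid / config.n_workers,
        mean_normalized_efficiency=mean,
        dispersion=disp,
        normalized=normalized,
        beta=float(beta),
        delta=float(delta),
        mode=config.mode,
        distribution=config.distribution,
        n_workers=config.n_workers,
        n_replicates=len(samples),
        replicate_argmax_fractions=k_grid[arg] / config.n_workers,
    )


def _argmax_last(values: np.ndarray) -> int:
    """Index of the maximum, exact ties broken toward the last position."""
    return len(values) - 1 - int(np.argmax(values[::-1]))


def optimal_active_fraction(curve: EfficiencyCurve) -> float:
    """Active fraction maximizing the mean curve; ties go to the largest k.

    The tie-break encodes that when idling saves nothing, the colony keeps
    everyone active.
    """
    i = _argmax_last(curve.mean_normalized_efficiency)
    return float(curve.k_values[i]) / curve.n_workers


def run_sweep(config: SweepConfig) -> SweepResult:
    """Optimal active fraction over the full (beta, delta) grid.

    For every cell the replicate curves are averaged pointwise and a single
    argmax is taken (matching a mean-curve readout rather than averaging
    per-replicate argmaxes). Deterministic given ``base_seed``.
    """
    k_grid = config.k_grid
    ratio_crn = config.common_random_numbers and config.mode is EfficiencyMode.RATIO
    if config.common_random_numbers:
        shared_perf = _prefix_matrix(run_replicates(config), k_grid)
        if ratio_crn:
            # mean of (perf/cost) / (perf_N/cost_N) over replicates factors
            # into mean(perf/perf_N) * cost_N/cost, since cost is the same
            # for every replicate; the sample-dependent factor is computed
            # once for the whole grid
            q_mean = (shared_perf / shared_perf[:, -1:]).mean(axis=0)

    rows = []
    cell = 0
    for beta in config.beta_grid:
        for delta in config.delta_grid:
            params = CostParameters(
                delta=float(delta), beta=float(beta), production_cost=config.production_cost
            )
            cost = np.asarray(cost_for_active_counts(params, config.n_workers, k_grid))
            if ratio_crn:
                mean = q_mean * (cost[-1] / cost)
            else:
                if config.common_random_numbers:
                    perf = shared_perf
                else:
                    perf = _prefix_matrix(run_replicates(config, cell=cell), k_grid)
                curves, _ = _curves_matrix(perf, cost, config.mode)
                mean = curves.mean(axis=0)
            i = _argmax_last(mean)
            rows.append(
                (float(beta), float(delta), float(k_grid[i]) / config.n_workers, float(mean[i]))
            )
            cell += 1
    grid = pd.DataFrame(
        rows, columns=["beta", "delta", "optimal_active_fraction", "efficiency_at_optimum"]
    )
    return SweepResult(grid=grid, config=config)
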