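"""Colony-level costs, performance and efficiency.

The colony pays a one-off production cost ``c_p`` per worker and a lifetime
maintenance cost expressed relative to production through two ratios:
``delta`` (maintenance of an active worker over its production cost) and
``beta`` (maintenance of an inactive worker over that of an active one).
With ``k`` of ``N`` workers active, total cost is::

    cost = c_p * N + delta * c_p * (k + beta * (N - k))

Only active workers contribute performance; the colony activates the ``k``
best performers, so colony performance is the sum of the ``k`` largest
individual draws. Efficiency is performance divided by cost (ratio mode) or
performance minus cost (difference mode), and curves over ``k`` are
normalized by the all-active value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .distributions import PerformanceSample

__all__ = [
    "CostParameters",
    "ActivityAllocation",
    "EfficiencyMode",
    "CurveResult",
    "colony_cost",
    "cost_for_active_counts",
    "colony_performance",
    "topk_prefix_sums",
    "colony_efficiency",
    "normalized_efficiency_curve",
]


@dataclass(frozen=True)
class CostParameters:
    """Cost model parameters.

    ``production_cost`` is the per-worker production cost ``c_p`` in
    arbitrary units; ``delta`` >= 0 is the maintenance/production ratio;
    ``beta`` in [0, 1] is the inactive/active maintenance ratio.
    """

    delta: float
    beta: float
    production_cost: float = 100.0

    def __post_init__(self) -> None:
        if not self.production_cost > 0:
            raise ValueError(f"production_cost must be > 0, got {self.production_cost}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")


@dataclass(frozen=True)
class ActivityAllocation:
    """Which ``n_active`` of ``n_total`` workers are active.

    ``active_indices`` identifies the activated workers; when built from a
    sample they are exactly the indices of the ``n_active`` largest
    performances, ties broken toward the lower worker index (stable sort).
    """

    n_active: int
    n_total: int
    active_indices: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.n_active <= self.n_total:
            raise ValueError(
                f"need 0 < n_active <= n_total, got "
                f"n_active={self.n_active}, n_total={self.n_total}"
            )
        if self.active_indices is not None:
            idx = np.asarray(self.active_indices, dtype=int)
            if idx.shape != (self.n_active,):
                raise ValueError("active_indices must have length n_active")
            object.__setattr__(self, "active_indices", idx)

    @property
    def n_inactive(self) -> int:
        return self.n_total - self.n_active

    @classmethod
    def from_sample(cls, sample: PerformanceSample, k: int) -> "ActivityAllocation":
        """Activate the ``k`` top performers of ``sample``."""
        if not 0 < k <= sample.n:
            raise ValueError(f"need 0 < k <= n={sample.n}, got k={k}")
        order = np.argsort(-sample.values, kind="stable")
        return cls(n_active=k, n_total=sample.n, active_indices=order[:k])


class EfficiencyMode(str, enum.Enum):
    """How efficiency combines performance and cost."""

    RATIO = "ratio"
    DIFFERENCE = "difference"


def colony_cost(params: CostParameters, allocation: ActivityAllocation) -> float:
    """Total colony cost for a given activity allocation.

    Production is paid once for every worker; maintenance scales with
    activity: ``c_p*N + delta*c_p*(k + beta*(N-k))``.
    """
    k, n = allocation.n_active, allocation.n_total
    cp = params.production_cost
    return cp * n + params.delta * cp * (k + params.beta * (n - k))


def cost_for_active_counts(
    params: CostParameters, n_total: int, k: np.ndarray | int
) -> np.ndarray | float:
    """Vectorized :func:`colony_cost` over active counts ``k``."""
    k = np.asarray(k, dtype=float)
    cp = params.production_cost
    return cp * n_total + params.delta * cp * (k + params.beta * (n_total - k))


def topk_prefix_sums(values: np.ndarray) -> np.ndarray:
    """Cumulative sums of ``values`` sorted in decreasing order.

    Entry ``j`` (0-based) is the best achievable performance with ``j + 1``
    active workers, so a whole efficiency curve costs one sort.
    """
    return np.cumsum(np.sort(np.asarray(values, dtype=float))[::-1])


def colony_performance(sample: PerformanceSample, k: int) -> float:
    """Sum of the ``k`` largest individual performances."""
    if not 0 < k <= sample.n:
        raise ValueError(f"need 0 < k <= n={sample.n}, got k={k}")
    return float(topk_prefix_sums(sample.values)[k - 1])


def colony_efficiency(
    sample: PerformanceSample,
    k: int,
    params: CostParameters,
    mode: EfficiencyMode = EfficiencyMode.RATIO,
) -> float:
    """Colony efficiency with the ``k`` best performers active."""
    mode = EfficiencyMode(mode)
    perf = colony_performance(sample, k)
    cost = colony_cost(params, ActivityAllocation(n_active=k, n_total=sample.n))
    if mode is EfficiencyMode.RATIO:
        return perf / cost
    return perf - cost


@dataclass(frozen=True, eq=False)
class CurveResult:
    """Efficiency as a function of the number of active workers, for one
    replicate.

    ``values`` are normalized by the all-active efficiency when
    ``normalized`` is True. In difference mode a non-positive all-active
    reference makes division meaningless; the raw (unnormalized) curve is
    then returned with ``normalized=False``.
    """

    k_values: np.ndarray
    values: np.ndarray
    normalized: bool


def normalized_efficiency_curve(
    sample: PerformanceSample,
    k_grid: np.ndarray,
    params: CostParameters,
    mode: EfficiencyMode = EfficiencyMode.RATIO,
) -> CurveResult:
    """Efficiency over ``k_grid``, normalized by the all-active value.

    ``k_grid`` must be increasing, lie within ``[1, n]`` and contain ``n``
    (the normalization reference); the ratio-mode curve equals exactly 1 at
    ``k = n``.
    """
    mode = EfficiencyMode(mode)
    k_grid = np.asarray(k_grid, dtype=int)
    if k_grid.ndim != 1 or k_grid.size == 0:
        raise ValueError("k_grid must be a non-empty 1-D integer sequence")
    if np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be strictly increasing")
    if k_grid[0] < 1 or k_grid[-1] > sample.n:
        raise ValueError(f"k_grid must lie within [1, {sample.n}]")
    if k_grid[-1] != sample.n:
        raise ValueError(f"k_grid must contain n={sample.n} as normalization reference")

    prefix = topk_prefix_sums(sample.values)
    perf = prefix[k_grid - 1]
    cost = cost_for_active_counts(params, sample.n, k_grid)

    if mode is EfficiencyMode.RATIO:
        eff = perf / cost
        return CurveResult(k_values=k_grid, values=eff / eff[-1], normalized=True)

    eff = perf - cost
    ref = eff[-1]
    if ref > 0:
        return CurveResult(k_values=k_grid, values=eff / ref, normalized=True)
    return CurveResult(k_values=k_grid, values=eff, normalized=False)
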