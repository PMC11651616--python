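"""Random individual-performance distributions on the unit interval.

Worker performance is modelled as a random draw on [0, 1]. Five families are
supported: a truncated normal, a truncated two-component normal mixture
("bimodal"), the standard uniform, and two power-transformed skewed
distributions (``u**(1/skewness)`` is left-skewed, ``1 - u**(1/skewness)``
right-skewed, with ``u`` standard uniform). Distributions whose parent has
mass outside [0, 1] are confined to the interval by one of two truncation
policies: *rejection* (resample until in range) or *clip* (clamp to the
nearest bound). The two policies yield visibly different spreads — rejection
removes the tails, clipping piles them up as atoms at 0 and 1 — so the policy
is part of the distribution specification.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import integrate, stats

__all__ = [
    "DistributionKind",
    "Truncation",
    "DistributionSpec",
    "PerformanceSample",
    "sample_performances",
    "analytic_moments",
]

# resample batches until this many rounds before declaring failure; with the
# parameter ranges admitted by DistributionSpec the in-range mass is far from
# zero and rejection terminates almost immediately
_MAX_REJECTION_ROUNDS = 1000


class DistributionKind(str, enum.Enum):
    """The five supported performance-distribution families."""

    NORMAL = "normal"
    BIMODAL = "bimodal"
    UNIFORM = "uniform"
    LEFT_SKEW = "left_skew"
    RIGHT_SKEW = "right_skew"


class Truncation(str, enum.Enum):
    """Policy confining a distribution to [0, 1]."""

    REJECTION = "rejection"
    CLIP = "clip"


#: default truncation policy per kind (only normal/bimodal need one)
_DEFAULT_TRUNCATION = {
    DistributionKind.NORMAL: Truncation.REJECTION,
    DistributionKind.BIMODAL: Truncation.CLIP,
}


@dataclass(frozen=True)
class DistributionSpec:
    """Specification of one individual-performance distribution.

    Parameters
    ----------
    kind
        One of ``normal``, ``bimodal``, ``uniform``, ``left_skew``,
        ``right_skew`` (enum or string).
    mean, sd
        Location and scale of the parent Gaussian (``normal`` only).
    mean1, sd1, mean2, sd2, weight1
        Component parameters and first-component weight of the parent
        Gaussian mixture (``bimodal`` only).
    skewness
        Positive exponent parameter of the power transform (skew kinds
        only); ``skewness = 1`` degenerates to the uniform.
    truncation
        ``rejection`` or ``clip``; meaningful for ``normal`` and
        ``bimodal`` only. Defaults: normal uses rejection, bimodal uses
        clipping (these reproduce spreads of 0.19 and 0.39 respectively).

    The support is fixed to the closed interval [0, 1].
    """

    kind: DistributionKind
    mean: float = 0.5
    sd: float = 0.2
    mean1: float = 0.1
    sd1: float = 0.2
    mean2: float = 0.9
    sd2: float = 0.2
    weight1: float = 0.5
    skewness: float = 4.0
    truncation: Truncation | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", DistributionKind(self.kind))
        if self.truncation is None:
            object.__setattr__(
                self, "truncation", _DEFAULT_TRUNCATION.get(self.kind)
            )
        elif self.kind in _DEFAULT_TRUNCATION:
            object.__setattr__(self, "truncation", Truncation(self.truncation))
        else:
            # uniform / skew kinds never leave [0, 1]; a policy is meaningless
            raise ValueError(
                f"truncation is only applicable to normal and bimodal kinds, "
                f"not {self.kind.value!r}"
            )
        if self.kind is DistributionKind.NORMAL and self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")
        if self.kind is DistributionKind.BIMODAL:
            if self.sd1 <= 0 or self.sd2 <= 0:
                raise ValueError(
                    f"component SDs must be > 0, got sd1={self.sd1}, sd2={self.sd2}"
                )
            if not 0.0 <= self.weight1 <= 1.0:
                raise ValueError(f"weight1 must lie in [0, 1], got {self.weight1}")
        if self.kind in (DistributionKind.LEFT_SKEW, DistributionKind.RIGHT_SKEW):
            if not self.skewness > 0:
                raise ValueError(f"skewness must be > 0, got {self.skewness}")

    def to_dict(self) -> dict[str, Any]:
        """Serialize to the flat key/value form used in config files."""
        d: dict[str, Any] = {"kind": self.kind.value}
        if self.kind is DistributionKind.NORMAL:
            d.update(mean=self.mean, sd=self.sd, truncation=self.truncation.value)
        elif self.kind is DistributionKind.BIMODAL:
            d.update(
                mean1=self.mean1,
                sd1=self.sd1,
                mean2=self.mean2,
                sd2=self.sd2,
                weight1=self.weight1,
                truncation=self.truncation.value,
            )
        elif self.kind in (DistributionKind.LEFT_SKEW, DistributionKind.RIGHT_SKEW):
            d["skewness"] = self.skewness
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DistributionSpec":
        allowed = {
            "kind", "mean", "sd", "mean1", "sd1", "mean2", "sd2",
            "weight1", "skewness", "truncation",
        }
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(
                f"unknown distribution key(s): {', '.join(sorted(unknown))}"
            )
        if "kind" not in d:
            raise ValueError("distribution block requires a 'kind' key")
        return cls(**d)


@dataclass(frozen=True, eq=False)
class PerformanceSample:
    """One replicate's vector of individual performances.

    ``values`` holds ``n`` reals in [0, 1], one per worker; ``seed_info``
    records the generator state at the moment of sampling so the draw can be
    reproduced bit-for-bit.
    """

    values: np.ndarray
    n: int
    seed_info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != self.n:
            raise ValueError(
                f"values must be a length-{self.n} vector, got shape {values.shape}"
            )
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            raise ValueError("performance values must lie in [0, 1]")


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _rejection_sample(draw, n: int, rng: np.random.Generator) -> np.ndarray:
    """Fill ``n`` values by resampling until every draw lies in [0, 1]."""
    out = np.empty(n)
    filled = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        if filled == n:
            return out
        batch = draw(n - filled, rng)
        keep = batch[(batch >= 0.0) & (batch <= 1.0)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    raise RuntimeError("rejection sampling failed to converge")  # pragma: no cover


def _draw_mixture(spec: DistributionSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    pick1 = rng.random(size) < spec.weight1
    x = rng.normal(spec.mean2, spec.sd2, size)
    n1 = int(pick1.sum())
    x[pick1] = rng.normal(spec.mean1, spec.sd1, n1)
    return x


def sample_performances(
    spec: DistributionSpec,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> PerformanceSample:
    """Draw ``n`` individual performances according to ``spec``.

    Parameters
    ----------
    spec
        The distribution to sample from.
    n
        Colony size (number of workers); must be >= 1.
    rng
        A :class:`numpy.random.Generator`, an integer seed, or ``None`` for
        OS entropy. The generator state before sampling is recorded in the
        returned sample's ``seed_info``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _as_rng(rng)
    seed_info = {"bit_generator": type(rng.bit_generator).__name__,
                 "state": rng.bit_generator.state}

    kind = spec.kind
    if kind is DistributionKind.UNIFORM:
        values = rng.random(n)
    elif kind is DistributionKind.LEFT_SKEW:
        values = rng.random(n) ** (1.0 / spec.skewness)
    elif kind is DistributionKind.RIGHT_SKEW:
        values = 1.0 - rng.random(n) ** (1.0 / spec.skewness)
    elif kind is DistributionKind.NORMAL:
        if spec.truncation is Truncation.REJECTION:
            values = _rejection_sample(
                lambda m, g: g.normal(spec.mean, spec.sd, m), n, rng
            )
        else:
            values = np.clip(rng.normal(spec.mean, spec.sd, n), 0.0, 1.0)
    elif kind is DistributionKind.BIMODAL:
        if spec.truncation is Truncation.REJECTION:
            values = _rejection_sample(
                lambda m, g: _draw_mixture(spec, m, g), n, rng
            )
        else:
            values = np.clip(_draw_mixture(spec, n, rng), 0.0, 1.0)
    else:  # pragma: no cover
        raise AssertionError(f"unhandled kind {kind}")

    return PerformanceSample(values=values, n=n, seed_info=seed_info)


# ---------------------------------------------------------------------------
# exact moments (test oracle for the samplers)


def _clipped_normal_raw_moments(mean: float, sd: float) -> tuple[float, float]:
    """First and second raw moments of clip(N(mean, sd), 0, 1).

    The clipped variable has density equal to the parent's on (0, 1) plus
    atoms at 0 and 1 carrying the out-of-range mass; the interior integrals
    are evaluated numerically.
    """
    dist = stats.norm(mean, sd)
    p_high = dist.sf(1.0)
    m1 = integrate.quad(lambda x: x * dist.pdf(x), 0.0, 1.0, limit=200)[0] + p_high
    m2 = integrate.quad(lambda x: x * x * dist.pdf(x), 0.0, 1.0, limit=200)[0] + p_high
    return m1, m2


def _truncnorm_raw_moments(mean: float, sd: float) -> tuple[float, float, float]:
    """(mass in [0,1], first, second raw moment) of N(mean, sd) restricted to [0,1]."""
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    tn = stats.truncnorm(a, b, loc=mean, scale=sd)
    m, v = tn.stats(moments="mv")
    mass = stats.norm(mean, sd).cdf(1.0) - stats.norm(mean, sd).cdf(0.0)
    return mass, float(m), float(v + m * m)


def analytic_moments(spec: DistributionSpec) -> tuple[float, float]:
    """Exact mean and standard deviation of the distribution in ``spec``.

    Closed forms are used where they exist (uniform, power-transformed skew
    kinds, rejection-truncated normal); the clipped cases go through numeric
    integration of the parent density plus boundary atoms. Serves as the
    independent oracle against which the samplers are validated.
    """
    kind = spec.kind
    if kind is DistributionKind.UNIFORM:
        return 0.5, math.sqrt(1.0 / 12.0)
    if kind in (DistributionKind.LEFT_SKEW, DistributionKind.RIGHT_SKEW):
        # X = U**(1/s)  =>  E[X^r] = s / (s + r)
        s = spec.skewness
        m1, m2 = s / (s + 1.0), s / (s + 2.0)
        var = m2 - m1 * m1
        mean = m1 if kind is DistributionKind.LEFT_SKEW else 1.0 - m1
        return mean, math.sqrt(var)
    if kind is DistributionKind.NORMAL:
        if spec.truncation is Truncation.REJECTION:
            _, m1, m2 = _truncnorm_raw_moments(spec.mean, spec.sd)
        else:
            m1, m2 = _clipped_normal_raw_moments(spec.mean, spec.sd)
        return m1, math.sqrt(m2 - m1 * m1)
    if kind is DistributionKind.BIMODAL:
        w = (spec.weight1, 1.0 - spec.weight1)
        comps = ((spec.mean1, spec.sd1), (spec.mean2, spec.sd2))
        if spec.truncation is Truncation.CLIP:
            # clipping commutes with mixing: moments are the weighted
            # component moments of the clipped components
            m1 = m2 = 0.0
            for wi, (mu, sd) in zip(w, comps):
                c1, c2 = _clipped_normal_raw_moments(mu, sd)
                m1 += wi * c1
                m2 += wi * c2
        else:
            # rejection restricts the mixture density to [0, 1] and
            # renormalizes; components contribute via their in-range mass
            mass = m1 = m2 = 0.0
            for wi, (mu, sd) in zip(w, comps):
                z, c1, c2 = _truncnorm_raw_moments(mu, sd)
                mass += wi * z
                m1 += wi * z * c1
                m2 += wi * z * c2
            m1 /= mass
            m2 /= mass
        return m1, math.sqrt(m2 - m1 * m1)
    raise AssertionError(f"unhandled kind {kind}")  # pragma: no cover
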