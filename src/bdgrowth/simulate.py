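"""Coalescence-time simulators for a sampled supercritical birth-death process.

A birth-death process starts from one individual; each individual gives birth
at rate ``lambda`` and dies at rate ``mu``, with net growth rate
``r = lambda - mu > 0``.  At time ``T`` a sample of ``n`` extant individuals
is taken; its genealogy has ``n - 1`` coalescence times ("depths"), measured
backward from the sampling time.  This module draws those depths under three
nested models:

* ``exact_finite_T`` -- the exact finite-horizon law (Harris / Lambert
  coalescent point process): a mixing variable Y on (0, 1) is drawn, and the
  depths are conditionally i.i.d. on (0, T) given Y.
* ``fixed_n_limit`` -- the T -> infinity limit at fixed n: a positive mixing
  variable Q is drawn, and the depths are ``T - (log Q + U_i)/r`` with U_i
  i.i.d. truncated-logistic given Q.
* ``large_n_limit`` -- the further n -> infinity limit: ``W ~ Exp(1)`` and
  standard-logistic U_i give ``T - (log(1/W) + log n + U_i)/r``.

All sampling is by closed-form inverse CDF; every function takes an explicit
``numpy.random.Generator`` (or a seed), never global state.  Depths from the
two limit models may fall outside (0, T) and are deliberately not clipped:
the estimators downstream depend only on pairwise differences, and clipping
would distort the laws being simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BDParams",
    "CoalescenceSample",
    "delta_T",
    "sample_Y",
    "sample_Q",
    "sample_U_trunc",
    "sample_coal_times_exact",
    "sample_coal_times_fixed_n",
    "sample_coal_times_large_n",
    "draw_birth_death_rates",
    "as_rng",
]


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Normalize a Generator / seed / None into a ``numpy.random.Generator``."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class BDParams:
    """Rates of a supercritical birth-death process.

    Parameters
    ----------
    birth_rate
        Per-individual birth rate ``lambda`` (> 0), per unit time.
    death_rate
        Per-individual death rate ``mu`` (>= 0), per unit time.

    The net growth rate ``r = lambda - mu`` must be positive (supercritical).
    """

    birth_rate: float
    death_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (self.birth_rate > 0):
            raise ValueError(f"birth rate must be > 0, got {self.birth_rate}")
        if not (self.death_rate >= 0):
            raise ValueError(f"death rate must be >= 0, got {self.death_rate}")
        if not (self.birth_rate > self.death_rate):
            raise ValueError(
                "process must be supercritical: birth rate "
                f"{self.birth_rate} <= death rate {self.death_rate}"
            )

    @property
    def growth_rate(self) -> float:
        """Net growth rate ``r = lambda - mu``."""
        return self.birth_rate - self.death_rate

    @classmethod
    def from_growth_rate(cls, growth_rate: float, birth_rate: float) -> "BDParams":
        """Construct from ``(r, lambda)``, setting ``mu = lambda - r``."""
        return cls(birth_rate=birth_rate, death_rate=birth_rate - growth_rate)


@dataclass(frozen=True)
class CoalescenceSample:
    """The ``n - 1`` coalescence depths of a sample of ``n`` individuals.

    ``depths`` are times measured backward from the sampling instant to each
    merge event.  ``horizon`` is the sampling time ``T`` (``math.inf`` for the
    unbounded limit models).  ``ordered`` is True when the depths are in a
    valid coalescent-point-process ladder order (conditionally i.i.d. draws
    are such an order).  ``model`` tags which law generated the sample.
    """

    depths: np.ndarray
    horizon: float
    ordered: bool = True
    model: str = "exact_finite_T"

    _MODELS = ("exact_finite_T", "fixed_n_limit", "large_n_limit", "data")

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "depths", depths)
        if depths.ndim != 1 or depths.size < 1:
            raise ValueError("depths must be a 1-D sequence of >= 1 times")
        if self.model not in self._MODELS:
            raise ValueError(f"unknown model tag {self.model!r}")
        if self.model == "exact_finite_T":
            if not (np.all(depths > 0) and np.all(depths < self.horizon)):
                raise ValueError("exact finite-T depths must lie in (0, T)")
        elif self.model == "fixed_n_limit":
            if not np.all(depths < self.horizon):
                raise ValueError("fixed-n limit depths must lie below T")

    @property
    def n(self) -> int:
        """Sample size ``n`` (number of tips; one more than merge events)."""
        return self.depths.size + 1


def delta_T(params: BDParams, T: float) -> float:
    """Probability ``delta_T`` that a single lineage alive at time T descends
    from the time-0 founder without any sampled coalescence, in the CPP law:

    ``delta_T = r e^{-rT} / (lambda (1 - e^{-rT}) + r e^{-rT})``.

    Strictly decreasing in T, equal to 1 at T = 0, tending to 0 as T grows.
    """
    if T < 0:
        raise ValueError(f"horizon T must be >= 0, got {T}")
    r, lam = params.growth_rate, params.birth_rate
    ert = math.exp(-r * T)
    return r * ert / (lam * (1.0 - ert) + r * ert)


def sample_Y(
    n: int,
    delta: float,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
):
    """Draw the finite-T mixing variable Y on (0, 1) with density
    ``f(y) = n delta y^{n-1} / (y + delta - y delta)^{n+1}``.

    The CDF is ``F(y) = (y / (y + delta (1 - y)))^n``; inverting gives
    ``Y = v delta / (1 - v (1 - delta))`` with ``v = u^{1/n}``.
    """
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    if not (0 < delta <= 1):
        raise ValueError(f"delta must lie in (0, 1], got {delta}")
    rng = as_rng(rng)
    v = rng.random(size) ** (1.0 / n)
    return v * delta / (1.0 - v * (1.0 - delta))


def sample_Q(
    n: int,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
):
    """Draw the fixed-n (T -> infinity) mixing variable Q on (0, infinity)
    with density ``f(q) = n q^{n-1} / (1 + q)^{n+1}``.

    The CDF is ``F(q) = (q / (1 + q))^n``, so ``Q = v / (1 - v)`` with
    ``v = u^{1/n}``.
    """
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    rng = as_rng(rng)
    v = rng.random(size) ** (1.0 / n)
    return v / (1.0 - v)


def sample_U_trunc(
    q,
    rng: np.random.Generator | int | None = None,
    size=None,
):
    """Draw from the standard logistic density truncated to ``(-log q, inf)``
    and renormalized by ``(1 + q)/q``.

    The logistic CDF at ``-log q`` is ``1/(1 + q)``, so a draw is
    ``logit(v)`` with ``v ~ Uniform(1/(1 + q), 1)``.  ``q`` may be a scalar
    or an array broadcastable against ``size``.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be > 0")
    rng = as_rng(rng)
    lo = 1.0 / (1.0 + q)
    v = rng.uniform(lo, 1.0, size=size)
    out = np.log(v / (1.0 - v))
    return out if out.shape else float(out)


def _depths_given_y(
    m: int, y: float, params: BDParams, T: float, rng: np.random.Generator
) -> np.ndarray:
    """m conditionally i.i.d. depths on (0, T) given Y = y, by the analytic
    inverse of the conditional CDF

    ``F(t | y) = g(T) (1 - e^{-rt}) / ((1 - e^{-rT}) g(t))``,
    ``g(t) = y lambda + (r - y lambda) e^{-rt}``.
    """
    r, lam = params.growth_rate, params.birth_rate
    E = math.exp(-r * T)
    ylam = y * lam
    g_T = ylam + (r - ylam) * E
    u = rng.random(m)
    k = u * (1.0 - E) / g_T
    x = (1.0 - k * ylam) / (1.0 + k * (r - ylam))
    return -np.log(x) / r


def sample_coal_times_exact(
    n: int,
    params: BDParams,
    T: float,
    rng: np.random.Generator | int | None = None,
) -> CoalescenceSample:
    """Exact finite-horizon coalescence depths: draw Y, then n - 1
    conditionally i.i.d. depths on (0, T) given Y.

    The returned order (the i.i.d. draw order) is a valid CPP ladder order.
    """
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    if not (T > 0):
        raise ValueError(f"horizon T must be > 0, got {T}")
    rng = as_rng(rng)
    delta = delta_T(params, T)
    y = float(sample_Y(n, delta, rng))
    depths = _depths_given_y(n - 1, y, params, T, rng)
    return CoalescenceSample(depths, horizon=T, ordered=True, model="exact_finite_T")


def sample_coal_times_fixed_n(
    n: int,
    growth_rate: float,
    T: float,
    rng: np.random.Generator | int | None = None,
) -> CoalescenceSample:
    """Fixed-n, T -> infinity depths ``H_i = T - (log Q + U_i)/r`` with
    Q from :func:`sample_Q` and U_i truncated-logistic given Q.

    ``U_i > -log Q`` forces every depth below T; depths may be negative.
    ``r (T - H)`` is pivotal: its law depends on n only.
    """
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    if not (growth_rate > 0):
        raise ValueError(f"growth rate must be > 0, got {growth_rate}")
    rng = as_rng(rng)
    q = float(sample_Q(n, rng))
    u = sample_U_trunc(q, rng, size=n - 1)
    depths = T - (math.log(q) + u) / growth_rate
    return CoalescenceSample(depths, horizon=T, ordered=True, model="fixed_n_limit")


def sample_coal_times_large_n(
    n: int,
    growth_rate: float,
    T: float,
    rng: np.random.Generator | int | None = None,
) -> CoalescenceSample:
    """Large-n depths ``H_i = T - (log(1/W) + log n + U_i)/r`` with
    ``W ~ Exp(1)`` and U_i i.i.d. standard logistic (unbounded support)."""
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    if not (growth_rate > 0):
        raise ValueError(f"growth rate must be > 0, got {growth_rate}")
    rng = as_rng(rng)
    w = rng.exponential()
    u = rng.logistic(size=n - 1)
    depths = T - (-math.log(w) + math.log(n) + u) / growth_rate
    return CoalescenceSample(depths, horizon=T, ordered=True, model="large_n_limit")


def draw_birth_death_rates(
    growth_rate: float, rng: np.random.Generator | int | None = None
) -> BDParams:
    """Draw rates for the simulation-study protocol: ``lambda ~ Uniform[r, 1+r]``
    and ``mu = lambda - r``, so the net growth rate is exactly ``r``."""
    if not (growth_rate > 0):
        raise ValueError(f"growth rate must be > 0, got {growth_rate}")
    rng = as_rng(rng)
    lam = rng.uniform(growth_rate, 1.0 + growth_rate)
    return BDParams(birth_rate=lam, death_rate=lam - growth_rate)
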