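"""Pivot-based confidence intervals for the growth rate.

Under the fixed-n, T -> infinity law the c = 1 pairwise estimator satisfies
``r_hat = r S_n`` with S_n a pivot whose distribution is free of r.  If
``q_lo`` and ``q_hi`` are the (1-level)/2 and 1-(1-level)/2 quantiles of S_n,
then ``P(r_hat/q_hi < r < r_hat/q_lo) = level`` exactly in that model, and
remains close to it under the exact finite-T law once T is moderately large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import growth_rate_estimate, sample_S
from .simulate import CoalescenceSample, as_rng

__all__ = ["QuantilePair", "quantiles_S", "confidence_interval"]


@dataclass(frozen=True)
class QuantilePair:
    """Monte Carlo quantiles of the pivot S_n used to invert the interval.

    ``q_lo < q_hi`` are the empirical (1-level)/2 and 1-(1-level)/2 quantiles
    (order-statistic linear interpolation) from ``mc_samples`` draws; ``seed``
    records provenance.
    """

    q_lo: float
    q_hi: float
    level: float
    n: int
    mc_samples: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.q_lo < self.q_hi):
            raise ValueError(f"need 0 < q_lo < q_hi, got ({self.q_lo}, {self.q_hi})")
        if not (0 < self.level < 1):
            raise ValueError(f"level must lie in (0, 1), got {self.level}")


def quantiles_S(
    n: int,
    level: float = 0.95,
    mc_samples: int = 10**6,
    rng: np.random.Generator | int | None = None,
    seed: int | None = None,
) -> QuantilePair:
    """Empirical quantiles of S_n from ``mc_samples`` Monte Carlo draws.

    Uses linear interpolation between adjacent order statistics (numpy's
    default quantile rule); the Monte Carlo error is O(1/sqrt(mc_samples)).
    """
    if n < 3:
        raise ValueError(f"S_n quantiles require n >= 3, got {n}")
    if mc_samples < 10**4:
        raise ValueError("mc_samples must be >= 10^4")
    if not (0 < level < 1):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    rng = as_rng(rng if rng is not None else seed)
    alpha = (1.0 - level) / 2.0
    # draw in chunks to bound memory at large n
    draws = []
    done = 0
    while done < mc_samples:
        m = min(200_000, mc_samples - done)
        draws.append(sample_S(n, rng, size=m))
        done += m
    s = np.concatenate(draws)
    q_lo, q_hi = np.quantile(s, [alpha, 1.0 - alpha])
    return QuantilePair(
        q_lo=float(q_lo),
        q_hi=float(q_hi),
        level=level,
        n=n,
        mc_samples=int(mc_samples),
        seed=seed,
    )


def confidence_interval(depths, qp: QuantilePair) -> tuple[float, float]:
    """Pivot interval ``(r_hat/q_hi, r_hat/q_lo)`` with ``r_hat`` the c = 1
    pairwise estimate.

    The interval always uses c = 1 internally (the pivot identity
    ``r_hat = r S_n``) regardless of which point estimator is reported
    alongside it.
    """
    if isinstance(depths, CoalescenceSample):
        depths = depths.depths
    depths = np.asarray(depths, dtype=float)
    if depths.size + 1 != qp.n:
        raise ValueError(
            f"quantile pair is for n = {qp.n} but depths imply n = {depths.size + 1}"
        )
    r1 = growth_rate_estimate(depths, c=1.0).r_hat
    return (r1 / qp.q_hi, r1 / qp.q_lo)
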