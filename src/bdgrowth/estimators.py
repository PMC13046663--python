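"""Point estimators of the birth-death net growth rate from coalescence times.

The central estimator is the pairwise family

    r_hat = c(n) (n-1)(n-2) / sum_{i,j} (H_i - H_j)^+ ,

where the H_i are the n - 1 coalescence depths and c(n) a dimensionless
calibration constant.  Because the order of the coalescence times carries no
information about r (any merge order is equally likely), this estimator is the
Rao-Blackwellized, order-free counterpart of the internal-branch-length
estimator ``r_hat = n / L_in``; it depends on the depths only through the sum
of absolute pairwise differences, a U-statistic.

Under the fixed-n, T -> infinity law the pairwise estimator factorizes as
``r_hat = r c(n) S_n`` with the pivot

    S_n = (n-1)(n-2) / sum_{i,j} (U_i - U_j)^+ ,

whose law is free of r.  The three calibrations are

* ``c_mse(n)  = E[S_n] / E[S_n^2]`` -- minimizes the mean squared error;
* ``c_bias(n) = 1 / E[S_n]``        -- makes r_hat unbiased for r;
* ``c_inv(n)  = E[1 / S_n]``        -- makes 1/r_hat unbiased for 1/r,
  with the closed form ``(n/(n-2)) (1 - H_{n-1}/(n-1))`` where H_{n-1} is
  the (n-1)-th harmonic number.

Also provided: the internal-branch-length estimator ``n / L_in`` and the
i.i.d. logistic location-scale MLE of ``1/r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .errors import ConvergenceError, DegenerateSampleError
from .simulate import CoalescenceSample, as_rng, sample_Q, sample_U_trunc

__all__ = [
    "EstimateResult",
    "ConstantsMC",
    "pairwise_plus_sum",
    "growth_rate_estimate",
    "c_inv",
    "sample_S",
    "estimate_constants_mc",
    "internal_branch_length_cpp",
    "rao_blackwell_internal_length",
    "r_lengths",
    "r_mle",
    "fit_logistic",
]

METHODS = ("mse", "bias", "inv", "lengths", "mle", "raw_c1")


@dataclass(frozen=True)
class EstimateResult:
    """A point estimate of the growth rate.

    ``method`` is one of ``mse``, ``bias``, ``inv`` (the pairwise family with
    the corresponding constant), ``raw_c1`` (pairwise, c = 1), ``lengths``
    (internal branch lengths) or ``mle``; ``c_used`` records the constant
    applied (1 for lengths / mle / raw_c1).
    """

    r_hat: float
    method: str
    c_used: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if not (self.r_hat > 0 and math.isfinite(self.r_hat)):
            raise ValueError(f"estimate must be finite and positive, got {self.r_hat}")


def _as_depths(depths) -> np.ndarray:
    if isinstance(depths, CoalescenceSample):
        depths = depths.depths
    arr = np.asarray(depths, dtype=float).ravel()
    if arr.size < 1:
        raise ValueError("need at least one coalescence time")
    return arr


def pairwise_plus_sum(depths) -> float:
    """``sum_{i} sum_{j} (H_i - H_j)^+`` over all ordered pairs, which equals
    ``sum_{i<j} |H_i - H_j|``.

    Permutation- and translation-invariant; scales linearly with the time
    unit.  Computed in O(m log m) from the order statistics:
    ``sum_{i<j} (h_(j) - h_(i)) = sum_k (2k - m + 1) h_(k)`` (0-based k).
    """
    h = np.sort(_as_depths(depths))
    m = h.size
    if m < 2:
        return 0.0
    w = 2.0 * np.arange(m) - (m - 1)
    return float(w @ h)


def _pairwise_plus_sum_rows(rows: np.ndarray) -> np.ndarray:
    """Row-wise pairwise_plus_sum for a 2-D array of depth vectors."""
    h = np.sort(rows, axis=1)
    m = rows.shape[1]
    w = 2.0 * np.arange(m) - (m - 1)
    return h @ w


def growth_rate_estimate(depths, c: float = 1.0, method: str | None = None) -> EstimateResult:
    """The pairwise estimator ``c (n-1)(n-2) / sum_{i,j} (H_i - H_j)^+``.

    ``depths`` are the n - 1 coalescence times of a sample of size n (in any
    order; the statistic is permutation-invariant).  Defined for n >= 3, but
    at n = 3 the single-pair denominator makes the estimator very heavy-tailed
    (E[S_3] is infinite); n >= 4 is the recommended minimum.  ``c`` defaults
    to 1 (the raw pivot scale used for confidence intervals).

    Raises
    ------
    DegenerateSampleError
        If all depths coincide (zero denominator).
    """
    arr = _as_depths(depths)
    n = arr.size + 1
    if n < 3:
        raise ValueError(f"pairwise estimator needs sample size n >= 3, got n = {n}")
    if not (c > 0):
        raise ValueError(f"constant c must be > 0, got {c}")
    denom = pairwise_plus_sum(arr)
    if denom <= 0:
        raise DegenerateSampleError(
            "all coalescence times are equal; the pairwise estimator is undefined"
        )
    if method is None:
        method = "raw_c1"
    return EstimateResult(
        r_hat=c * (n - 1) * (n - 2) / denom, method=method, c_used=c, n=n
    )


def c_inv(n: int) -> float:
    """Exact reciprocal-unbiased constant
    ``c_inv(n) = (n/(n-2)) (1 - (1/(n-1)) sum_{k=1}^{n-1} 1/k)``.

    Tends to 1 as n grows; ``c_inv(3) = 3/4``, ``c_inv(5) = 115/144``.
    """
    if n < 3:
        raise ValueError(f"c_inv requires n >= 3, got {n}")
    harmonic = float(np.sum(1.0 / np.arange(1, n)))
    return (n / (n - 2)) * (1.0 - harmonic / (n - 1))


def sample_S(
    n: int,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
):
    """Draw the pivot ``S_n = (n-1)(n-2) / sum_{i,j}(U_i - U_j)^+`` under the
    fixed-n, T -> infinity law (Q mixing + truncated logistic U's).

    Returns a scalar, or an array of ``size`` independent draws.  Defined for
    n >= 3; at n = 3 the pivot is heavy-tailed (infinite mean).
    """
    if n < 3:
        raise ValueError(f"S_n requires n >= 3, got {n}")
    rng = as_rng(rng)
    scalar = size is None
    m = 1 if scalar else int(size)
    q = np.asarray(sample_Q(n, rng, size=m), dtype=float)
    u = sample_U_trunc(q[:, None], rng, size=(m, n - 1))
    s = (n - 1) * (n - 2) / _pairwise_plus_sum_rows(u)
    return float(s[0]) if scalar else s


@dataclass(frozen=True)
class ConstantsMC:
    """Monte Carlo estimates of the three calibration constants for one n,
    each with its standard error (delta method for the two ratios)."""

    n: int
    mc_samples: int
    c_mse: float
    c_bias: float
    c_inv: float
    se_c_mse: float
    se_c_bias: float
    se_c_inv: float


def estimate_constants_mc(
    n: int,
    mc_samples: int = 10**6,
    rng: np.random.Generator | int | None = None,
    chunk: int = 200_000,
) -> ConstantsMC:
    """Estimate ``c_mse = E[S]/E[S^2]``, ``c_bias = 1/E[S]`` and
    ``c_inv = E[1/S]`` from ``mc_samples`` draws of :func:`sample_S`.

    Draws are processed in chunks to bound memory at large n.  The n = 3
    moments are infinite in theory; Monte Carlo values for n = 3 are reported
    but should be treated as unstable.
    """
    if n < 3:
        raise ValueError(f"constants require n >= 3, got {n}")
    if mc_samples < 10**4:
        raise ValueError("mc_samples must be >= 10^4 for usable standard errors")
    rng = as_rng(rng)
    N = int(mc_samples)
    s1 = s2 = s3 = s4 = inv1 = inv2 = 0.0
    done = 0
    while done < N:
        m = min(chunk, N - done)
        s = sample_S(n, rng, size=m)
        s1 += float(np.sum(s))
        s2 += float(np.sum(s**2))
        s3 += float(np.sum(s**3))
        s4 += float(np.sum(s**4))
        inv = 1.0 / s
        inv1 += float(np.sum(inv))
        inv2 += float(np.sum(inv**2))
        done += m
    m1, m2, m3, m4 = s1 / N, s2 / N, s3 / N, s4 / N
    i1, i2 = inv1 / N, inv2 / N
    var_m1 = (m2 - m1**2) / N
    var_m2 = (m4 - m2**2) / N
    cov_m1m2 = (m3 - m1 * m2) / N
    c_mse = m1 / m2
    # delta method for the ratio m1/m2
    var_cmse = (
        var_m1 / m2**2 + (m1**2 / m2**4) * var_m2 - 2.0 * (m1 / m2**3) * cov_m1m2
    )
    c_bias = 1.0 / m1
    var_cbias = var_m1 / m1**4
    c_inv_mc = i1
    var_cinv = (i2 - i1**2) / N
    return ConstantsMC(
        n=n,
        mc_samples=N,
        c_mse=c_mse,
        c_bias=c_bias,
        c_inv=c_inv_mc,
        se_c_mse=math.sqrt(max(var_cmse, 0.0)),
        se_c_bias=math.sqrt(max(var_cbias, 0.0)),
        se_c_inv=math.sqrt(max(var_cinv, 0.0)),
    )


def internal_branch_length_cpp(ordered_depths) -> float:
    """Total internal branch length of the ladder (coalescent point process)
    genealogy built from depths in CPP order ``H_1 .. H_{n-1}``:

    ``(max_i H_i - H_1) + sum_{i=1}^{n-2} (H_i - H_{i+1})^+``.

    Order-dependent by design (the CPP order determines the tree shape);
    translation-invariant.
    """
    h = _as_depths(ordered_depths)
    if h.size == 1:
        return 0.0
    first_term = float(np.max(h) - h[0])
    steps = h[:-1] - h[1:]
    return first_term + float(np.sum(steps[steps > 0]))


def rao_blackwell_internal_length(depths) -> float:
    """Conditional expectation of the CPP internal branch length given the
    order statistics (averaged over all equally likely merge orders):

    ``(H_(n-1) - mean(H)) + (1/(n-1)) sum_{i<j} |H_i - H_j|``.

    Permutation-invariant; equals the exact average of
    :func:`internal_branch_length_cpp` over all (n-1)! orderings.
    """
    h = _as_depths(depths)
    m = h.size
    return float(np.max(h) - np.mean(h)) + pairwise_plus_sum(h) / m


def r_lengths(internal_length: float, n: int) -> EstimateResult:
    """Internal-branch-length estimator ``r_hat = n / L_in``.

    ``L_in`` is the total internal branch length of the genealogy of the n
    sampled individuals (its expectation tends to ``(n/r)(1 - 1/(n-1))`` for
    large T, hence inversely proportional to r).
    """
    if n < 3:
        raise ValueError(f"r_lengths requires n >= 3, got {n}")
    if not (internal_length > 0):
        raise DegenerateSampleError(
            f"internal branch length must be > 0, got {internal_length}"
        )
    return EstimateResult(r_hat=n / internal_length, method="lengths", c_used=1.0, n=n)


def _logistic_negloglik(theta: np.ndarray, h: np.ndarray):
    """Negative log-likelihood and gradient of the i.i.d. logistic
    location-scale model in (a, log b)."""
    a, logb = theta
    b = math.exp(logb)
    z = (h - a) / b
    # log f(z) = z - 2 log(1 + e^z); use log1p(exp) via softplus for stability
    sp = np.logaddexp(0.0, z)
    nll = -(np.sum(z - 2.0 * sp) - h.size * logb)
    sig = special.expit(z)
    dl_dz = 1.0 - 2.0 * sig
    grad_a = np.sum(dl_dz) / b
    grad_logb = np.sum(dl_dz * z) + h.size
    return nll, np.array([grad_a, grad_logb])


def fit_logistic(depths) -> tuple[float, float]:
    """Maximum-likelihood fit of the i.i.d. logistic location-scale family.

    BFGS on ``(a, log b)`` with analytic gradient, from the moment start
    ``a0 = mean(H)``, ``b0 = sd(H) sqrt(3)/pi``; converged when the gradient
    norm falls below 1e-8.  Returns ``(location, scale)``.

    Raises
    ------
    DegenerateSampleError
        If all values are equal (the scale is not estimable).
    ConvergenceError
        If the optimizer stalls away from a stationary point.
    """
    h = _as_depths(depths)
    if h.size < 2:
        raise ValueError("logistic fit needs at least two values")
    sd = float(np.std(h))
    if sd == 0.0:
        raise DegenerateSampleError("all values are equal; logistic MLE undefined")
    x0 = np.array([float(np.mean(h)), math.log(sd * math.sqrt(3.0) / math.pi)])
    res = optimize.minimize(
        _logistic_negloglik,
        x0,
        args=(h,),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if not res.success and float(np.linalg.norm(res.jac)) > 1e-6:
        raise ConvergenceError(f"logistic MLE did not converge: {res.message}")
    return float(res.x[0]), float(math.exp(res.x[1]))


def r_mle(depths) -> EstimateResult:
    """Logistic maximum-likelihood estimator of the growth rate.

    Under the large-n law the depths are (conditionally) ``H_i = a + b U_i``
    with U_i standard logistic and ``b = 1/r``; the fit treats the depths as
    i.i.d. from that location-scale family and returns ``r_hat = 1/b_hat``.
    """
    h = _as_depths(depths)
    n = h.size + 1
    if n < 3:
        raise ValueError(f"logistic MLE requires n >= 3, got n = {n}")
    _, b_hat = fit_logistic(h)
    return EstimateResult(r_hat=1.0 / b_hat, method="mle", c_used=1.0, n=n)
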