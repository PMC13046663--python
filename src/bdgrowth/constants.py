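"""Calibration-constant and quantile tables, plus the high-level estimator
dispatch used by the CLI and the simulation study.

A table of Monte Carlo constants (c_mse, c_bias), the exact c_inv, and the
0.025/0.975 pivot quantiles is shipped for a grid of sample sizes; any other
n is computed on demand.  Every Monte Carlo entry records the number of draws
and the seed that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators
from .confidence import QuantilePair, quantiles_S
from .errors import BDGrowthError
from .estimators import EstimateResult, c_inv, estimate_constants_mc
from .simulate import CoalescenceSample, as_rng

__all__ = ["ConstantsTable", "point_estimate", "default_table"]

_COLUMNS = ["n", "c_mse", "c_bias", "c_inv", "q025", "q975", "mc_samples", "seed"]


@dataclass
class ConstantsTable:
    """Per-n calibration constants and S_n quantiles.

    ``c_inv`` entries are the exact closed form; ``c_mse``, ``c_bias``,
    ``q025`` and ``q975`` are Monte Carlo values from ``mc_samples`` draws of
    the pivot S_n with the recorded seed.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"constants table is missing columns {sorted(missing)}")
        f = self.frame
        bad = f[(f.c_mse > f.c_bias) | (f.q025 >= f.q975) | (f.q025 <= 0)]
        if len(bad):
            raise ValueError(
                f"invalid constants rows for n = {sorted(bad.n.astype(int))}: "
                "need c_mse <= c_bias and 0 < q025 < q975"
            )
        self.frame = f.astype({"n": int, "mc_samples": int}).set_index(
            f.n.astype(int), drop=False
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConstantsTable":
        return cls(pd.read_csv(path, comment="#"))

    def save(self, path: str | Path) -> None:
        self.frame[_COLUMNS].to_csv(path, index=False)

    def __contains__(self, n: int) -> bool:
        return int(n) in self.frame.index

    def row(self, n: int) -> pd.Series:
        if n not in self:
            raise KeyError(
                f"no constants tabulated for n = {n}; use ensure() to compute them"
            )
        return self.frame.loc[int(n)]

    def constant(self, n: int, method: str) -> float:
        """The calibration constant for one of the pairwise methods."""
        if method == "raw_c1":
            return 1.0
        if method == "inv":
            return c_inv(n)
        if method not in ("mse", "bias"):
            raise ValueError(f"no constant for method {method!r}")
        return float(self.row(n)[f"c_{method}"])

    def quantile_pair(self, n: int, level: float = 0.95) -> QuantilePair:
        if abs(level - 0.95) > 1e-12:
            raise ValueError("the shipped table stores 95% quantiles only")
        row = self.row(n)
        return QuantilePair(
            q_lo=float(row.q025),
            q_hi=float(row.q975),
            level=0.95,
            n=int(n),
            mc_samples=int(row.mc_samples),
            seed=int(row.seed),
        )

    def ensure(
        self,
        n: int,
        mc_samples: int = 10**6,
        seed: int | None = None,
    ) -> pd.Series:
        """Return the row for ``n``, computing and caching it if absent."""
        if n in self:
            return self.row(n)
        row = compute_row(n, mc_samples=mc_samples, seed=seed)
        self.frame = pd.concat([self.frame, row.to_frame().T]).sort_index()
        self.frame = self.frame.astype({"n": int, "mc_samples": int})
        return self.row(n)


def compute_row(n: int, mc_samples: int = 10**6, seed: int | None = None) -> pd.Series:
    """One constants-table row for sample size n: Monte Carlo c_mse/c_bias,
    exact c_inv, and Monte Carlo 0.025/0.975 quantiles of S_n."""
    rng = as_rng(seed)
    mc = estimate_constants_mc(n, mc_samples=mc_samples, rng=rng)
    qp = quantiles_S(n, level=0.95, mc_samples=mc_samples, rng=rng)
    return pd.Series(
        {
            "n": int(n),
            "c_mse": mc.c_mse,
            "c_bias": mc.c_bias,
            "c_inv": c_inv(n),
            "q025": qp.q_lo,
            "q975": qp.q_hi,
            "mc_samples": int(mc_samples),
            "seed": -1 if seed is None else int(seed),
        },
        name=int(n),
    )


_default: ConstantsTable | None = None


def default_table() -> ConstantsTable:
    """The table shipped with the package (cached per process)."""
    global _default
    if _default is None:
        with resources.as_file(
            resources.files("bdgrowth") / "data" / "constants_table.csv"
        ) as path:
            _default = ConstantsTable.load(path)
    return _default


def point_estimate(
    sample,
    method: str = "inv",
    table: ConstantsTable | None = None,
) -> EstimateResult:
    """Estimate the growth rate from a sample of coalescence times.

    ``sample`` is a :class:`~bdgrowth.simulate.CoalescenceSample` or a plain
    sequence of depths.  ``method`` is one of:

    * ``mse`` / ``bias`` / ``inv`` -- the pairwise estimator with the
      corresponding calibration constant (``inv`` is the recommended default:
      exactly computable constant, mode near the true rate);
    * ``raw_c1`` -- the uncalibrated pairwise pivot estimate;
    * ``lengths`` -- ``n / L_in`` from the CPP internal branch length
      (requires depths in a valid ladder order);
    * ``mle`` -- the i.i.d. logistic location-scale MLE.
    """
    if isinstance(sample, CoalescenceSample):
        depths, ordered = sample.depths, sample.ordered
    else:
        depths, ordered = np.asarray(sample, dtype=float), True
    n = depths.size + 1
    if method == "lengths":
        if not ordered:
            raise BDGrowthError(
                "the lengths estimator needs depths in CPP (ladder) order"
            )
        L = estimators.internal_branch_length_cpp(depths)
        return estimators.r_lengths(L, n)
    if method == "mle":
        return estimators.r_mle(depths)
    if method == "inv":
        c = c_inv(n)
    elif method == "raw_c1":
        c = 1.0
    elif method in ("mse", "bias"):
        table = table if table is not None else default_table()
        c = table.constant(n, method)
    else:
        raise ValueError(f"unknown method {method!r}")
    return estimators.growth_rate_estimate(depths, c=c, method=method)
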