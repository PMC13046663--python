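"""Simulation study harness: estimator comparison, CI coverage, and
constant-sensitivity curves.

The protocol mirrors the estimator-comparison experiments: for each scenario
(n, r, T) the birth rate is drawn ``lambda ~ Uniform[r, 1+r]`` with
``mu = lambda - r``, coalescence times are simulated (exact finite-T by
default), every requested estimator is applied to the same sample (common
random numbers sharpen the paired comparisons), and RMSE, MAE and bias are
summarized over replicates.  Degenerate replicates -- possible only through
numeric ties -- are dropped from summaries with a logged count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as _constants
from .confidence import QuantilePair, confidence_interval
from .errors import BDGrowthError
from .estimators import growth_rate_estimate, pairwise_plus_sum
from .simulate import (
    as_rng,
    draw_birth_death_rates,
    sample_coal_times_exact,
    sample_coal_times_fixed_n,
    sample_coal_times_large_n,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_simulation_study",
    "coverage_experiment",
    "constant_sensitivity",
    "simulate_sample",
]

ESTIMATORS = ("mse", "bias", "inv", "lengths", "mle")
SAMPLERS = ("exact", "fixed_n", "large_n")


def simulate_sample(sampler: str, n: int, r: float, T: float, rng):
    """One coalescence-time sample under the named model, with the study's
    rate protocol (``lambda ~ U[r, 1+r]``) for the exact sampler."""
    if sampler == "exact":
        params = draw_birth_death_rates(r, rng)
        return sample_coal_times_exact(n, params, T, rng)
    if sampler == "fixed_n":
        return sample_coal_times_fixed_n(n, r, T, rng)
    if sampler == "large_n":
        return sample_coal_times_large_n(n, r, T, rng)
    raise ValueError(f"unknown sampler {sampler!r}; expected one of {SAMPLERS}")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one estimator-comparison study."""

    n_values: tuple[int, ...]
    r_values: tuple[float, ...]
    T_values: tuple[float, ...]
    replicates: int = 1000
    estimators: tuple[str, ...] = ESTIMATORS
    seed: int = 0
    sampler: str = "exact"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (self.n_values and self.r_values and self.T_values):
            raise ValueError("all scenario grids must be non-empty")
        unknown = set(self.estimators) - set(ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators {sorted(unknown)}")
        if self.sampler not in SAMPLERS:
            raise ValueError(f"unknown sampler {self.sampler!r}")

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Read a flat ``key = value`` config file (comma-separated grids)."""
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
        def grid(key, cast):
            return tuple(cast(v) for v in kv[key].split(","))
        return cls(
            n_values=grid("n_values", int),
            r_values=grid("r_values", float),
            T_values=grid("T_values", float),
            replicates=int(kv.get("replicates", 1000)),
            estimators=tuple(kv.get("estimators", ",".join(ESTIMATORS)).split(",")),
            seed=int(kv.get("seed", 0)),
            sampler=kv.get("sampler", "exact"),
        )


@dataclass
class StudyResult:
    """Long-format per-replicate estimates plus per-scenario summaries.

    ``long`` columns: n, r, T, estimator, replicate, r_hat (NaN when the
    replicate was degenerate for that estimator).
    ``summary`` columns: n, r, T, estimator, rmse, mae, bias, n_degenerate.
    """

    long: pd.DataFrame
    summary: pd.DataFrame
    seed: int

    def save(self, long_path, summary_path) -> None:
        for path, frame in ((long_path, self.long), (summary_path, self.summary)):
            with open(path, "w") as fh:
                fh.write(f"# seed = {self.seed}\n")
                frame.to_csv(fh, index=False)


def summarize_long(long: pd.DataFrame) -> pd.DataFrame:
    """Recompute the scenario summaries (RMSE, MAE, bias, degenerate count)
    from the long records."""
    rows = []
    for (n, r, T, est), grp in long.groupby(
        ["n", "r", "T", "estimator"], sort=True
    ):
        r_hat = grp.r_hat.to_numpy()
        ok = r_hat[np.isfinite(r_hat)]
        err = ok - r
        rows.append(
            {
                "n": n,
                "r": r,
                "T": T,
                "estimator": est,
                "rmse": float(np.sqrt(np.mean(err**2))) if ok.size else np.nan,
                "mae": float(np.mean(np.abs(err))) if ok.size else np.nan,
                "bias": float(np.mean(err)) if ok.size else np.nan,
                "n_degenerate": int(np.sum(~np.isfinite(r_hat))),
            }
        )
    return pd.DataFrame(rows)


def run_simulation_study(
    config: StudyConfig, table: _constants.ConstantsTable | None = None
) -> StudyResult:
    """Run the full study described by ``config``; deterministic given its seed."""
    table = table if table is not None else _constants.default_table()
    rng = as_rng(config.seed)
    records = []
    for n in config.n_values:
        for r in config.r_values:
            for T in config.T_values:
                for rep in range(config.replicates):
                    sample = simulate_sample(config.sampler, n, r, T, rng)
                    for est in config.estimators:
                        try:
                            r_hat = _constants.point_estimate(
                                sample, method=est, table=table
                            ).r_hat
                        except BDGrowthError:
                            r_hat = np.nan
                        records.append(
                            {
                                "n": n,
                                "r": r,
                                "T": T,
                                "estimator": est,
                                "replicate": rep,
                                "r_hat": r_hat,
                            }
                        )
    long = pd.DataFrame(records)
    return StudyResult(long=long, summary=summarize_long(long), seed=config.seed)


def coverage_experiment(
    n: int,
    r: float,
    T: float,
    replicates: int,
    qp: QuantilePair,
    rng=None,
    sampler: str = "exact",
) -> tuple[float, float]:
    """Empirical coverage of the pivot interval: the fraction of simulated
    samples whose interval contains r, with its binomial standard error."""
    rng = as_rng(rng)
    hits = 0
    for _ in range(replicates):
        sample = simulate_sample(sampler, n, r, T, rng)
        lo, hi = confidence_interval(sample, qp)
        hits += lo < r < hi
    p = hits / replicates
    se = math.sqrt(max(p * (1.0 - p), 1e-12) / replicates)
    return p, se


def constant_sensitivity(
    n: int,
    r: float,
    T: float,
    c_grid,
    replicates: int,
    rng=None,
    sampler: str = "exact",
) -> pd.DataFrame:
    """RMSE / MAE / bias of the pairwise estimator as a function of its
    constant c, on a shared set of simulated samples (common random numbers:
    each r_hat is linear in c, so one simulation serves the whole grid)."""
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(c_grid <= 0):
        raise ValueError("all grid constants must be > 0")
    rng = as_rng(rng)
    base = np.empty(replicates)  # r_hat at c = 1 per replicate
    for i in range(replicates):
        sample = simulate_sample(sampler, n, r, T, rng)
        base[i] = growth_rate_estimate(sample.depths, c=1.0).r_hat
    rows = []
    for c in c_grid:
        err = c * base - r
        rows.append(
            {
                "c": float(c),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "mae": float(np.mean(np.abs(err))),
                "bias": float(np.mean(err)),
            }
        )
    return pd.DataFrame(rows)
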