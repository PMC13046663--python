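# bdgrowth

Growth-rate estimation for exponentially expanding populations — cancer
clones, clonal hematopoiesis, early epidemic spread — from the genealogy of a
**small** sample of individuals.

## The problem

A supercritical birth–death process (per-individual birth rate λ, death rate
μ, net growth rate r = λ − μ > 0) is sampled at time T: n individuals are
drawn uniformly from the extant population and their genealogical tree, an
ultrametric tree with n − 1 coalescence times H₁, …, H₍ₙ₋₁₎ (measured
backward from sampling), is assumed known. The task is to estimate r from
those coalescence times. Existing analytical estimators — the
internal-branch-length estimator r̂ = n/Lⁱⁿ and a logistic MLE — are derived
from large-n asymptotics and degrade for the small samples (n ≲ 20) typical
of single-cell clone studies.

## The estimator

Because every merge order of the lineages is equally likely regardless of r,
the order statistics of the coalescence times are sufficient, and
Rao–Blackwellizing the internal-branch-length estimator leads to the
order-free pairwise family

    r̂ = c(n) · (n−1)(n−2) / Σᵢ Σⱼ (Hᵢ − Hⱼ)⁺

where the double sum runs over ordered pairs and c(n) is a calibration
constant. Under the fixed-n, T → ∞ coalescent-point-process law, r̂ = r·c(n)·Sₙ
with a pivot Sₙ whose distribution is free of r, so c(n) can target

- **c_mse(n) = E[Sₙ]/E[Sₙ²]** — minimum mean squared error,
- **c_bias(n) = 1/E[Sₙ]** — unbiased for r,
- **c_inv(n) = E[1/Sₙ] = (n/(n−2))·(1 − H₍ₙ₋₁₎/(n−1))** — unbiased for 1/r,
  available in closed form (H₍ₙ₋₁₎ the harmonic number),

and the Sₙ quantiles invert into the exact-level confidence interval
[r̂/q₀.₉₇₅, r̂/q₀.₀₂₅] (with c = 1). The package also implements the exact
finite-T simulator of the coalescence times and its two limit approximations,
the n/Lⁱⁿ and logistic-MLE baselines, Newick I/O for ultrametric genealogies,
and a simulation-study harness.

## Worked example

```python
import numpy as np
from bdgrowth import (parse_newick, coalescence_depths, point_estimate,
                      default_table, confidence_interval)

tree = parse_newick("(((A:2.1,B:2.1):5.4,(C:3.0,D:3.0):4.5):4.5,"
                    "(E:9.9,F:9.9):2.1);")       # branch lengths in years
depths = coalescence_depths(tree)                # [12.0, 9.9, 7.5, 3.0, 2.1]
result = point_estimate(depths, method="inv")    # c_inv(6) = 0.8150
lo, hi = confidence_interval(depths, default_table().quantile_pair(6))
print(result.r_hat, (lo, hi))
```

prints

```
r_hat = 0.305 per year      95% CI = (0.101, 0.602)
```

i.e. the clone's population e-folds roughly every 3.3 years, with the wide
interval reflecting that only five merge times were observed. The scripts in
`examples/` walk through each capability — simulation, estimator comparison,
interval coverage, calibration constants — and print the numbers they
compute; `examples/estimator_comparison.py`, for instance, reproduces the
small-sample ordering (RMSE lowest for the mse-calibrated variant, near-zero
bias for the bias-calibrated one, upward bias for the branch-length and MLE
baselines) over 1000 simulated genealogies at n = 5.

A `bdgrowth` console script exposes the same operations from the shell:

```bash
bdgrowth simulate --n 10 --r 1 --t 40 --seed 1 --out depths.csv
bdgrowth estimate depths.csv --method inv
```

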