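# Methods

## Model

A supercritical birth–death process starts from one individual at time 0;
each individual independently gives birth at rate λ and dies at rate μ, with
net growth rate r = λ − μ > 0 (units: events per individual per unit time).
At time T, n extant individuals are sampled uniformly; their genealogy is an
ultrametric binary tree whose n − 1 internal nodes sit at coalescence depths
H₁, …, H₍ₙ₋₁₎, measured backward from the sampling instant (tips at depth 0).
All individuals share the same rates (neutrality), and the time axis is
assumed calibrated (e.g. via mutation rate or patient age); only r — not λ
and μ separately — is identified by the methods here.

## Coalescence-time laws and simulators (`bdgrowth.simulate`)

The sampled genealogy is a coalescent point process: with

    δ_T = r e^{−rT} / (λ(1 − e^{−rT}) + r e^{−rT}),

a mixing variable Y on (0, 1) has density n δ y^{n−1}/(y + δ − yδ)^{n+1},
and given Y = y the depths are i.i.d. on (0, T) with density proportional to
e^{−rt}/(yλ + (r − yλ)e^{−rt})². Two successive approximations are
implemented alongside the exact law:

- **fixed-n, T → ∞**: a mixing variable Q with density n q^{n−1}/(1+q)^{n+1},
  then Hᵢ = T − (log Q + Uᵢ)/r with Uᵢ i.i.d. standard-logistic truncated to
  (−log Q, ∞);
- **large-n**: W ~ Exp(1), Hᵢ = T − (log(1/W) + log n + Uᵢ)/r with Uᵢ i.i.d.
  standard logistic.

All sampling is by closed-form inverse CDF. The ones not standard:
F_Q(q) = (q/(1+q))ⁿ inverts to Q = v/(1−v) with v = u^{1/n};
F_Y(y) = (y/(y + δ(1−y)))ⁿ inverts analogously; the truncated logistic is
logit(v) with v uniform on (1/(1+Q), 1); and the exact conditional depth CDF

    F(t | y) = g(T)(1 − e^{−rt}) / ((1 − e^{−rT}) g(t)),  g(t) = yλ + (r − yλ)e^{−rt}

inverts to e^{−rt} = (1 − k·yλ)/(1 + k(r − yλ)) with k = u(1 − e^{−rT})/g(T),
an expression with no cancellation for any sign of r − yλ, so no numeric
fallback is needed. Each closed form is validated in the test suite by
Kolmogorov–Smirnov comparison against quadrature of the stated density.
Depths from the two limit models can fall outside (0, T); they are not
clipped, since the estimators depend only on pairwise differences and
clipping would distort the simulated laws. Every sampler takes an explicit
`numpy.random.Generator`; nothing uses global random state.

The simulation-study protocol draws λ uniformly on [r, 1+r] and sets
μ = λ − r, so scenarios are indexed by the growth rate alone.

## Estimators (`bdgrowth.estimators`)

The pairwise family r̂ = c(n)(n−1)(n−2)/ΣᵢΣⱼ(Hᵢ − Hⱼ)⁺ arises by
Rao–Blackwellization: the merge order of the lineages is uniform regardless
of r, so the order statistics of the depths are sufficient, and averaging the
order-dependent CPP internal branch length

    Lⁿᵢₙ = (maxᵢ Hᵢ − H₁) + Σᵢ (Hᵢ − Hᵢ₊₁)⁺

over all (n−1)! orders yields (H₍ₙ₋₁₎ − H̄) + (1/(n−1))Σᵢ<ⱼ|Hᵢ − Hⱼ|
(`rao_blackwell_internal_length`, verified against brute-force permutation
averaging to 1e−12). The estimator keeps only the dominant pairwise term,
treating all pairs symmetrically; the first term would double-weight pairs
involving the deepest merge.

Under the fixed-n law r̂ = r·c(n)·Sₙ with the r-free pivot
Sₙ = (n−1)(n−2)/ΣΣ(Uᵢ − Uⱼ)⁺. The calibrations c_mse = E[S]/E[S²] and
c_bias = 1/E[S] are Monte Carlo estimates (delta-method standard errors);
c_inv = E[1/S] has the closed form (n/(n−2))(1 − H₍ₙ₋₁₎/(n−1)). The pairwise
sum is computed in O(m log m) from order statistics, Σᵢ<ⱼ(h₍ⱼ₎ − h₍ᵢ₎) =
Σₖ(2k − m + 1)h₍ₖ₎.

Baselines: `r_lengths` (n/Lⁱⁿ) and `r_mle`, an i.i.d. logistic
location–scale maximum-likelihood fit (the large-n law makes the depths
conditionally logistic with scale 1/r). The MLE maximizes the log-likelihood
over (a, log b) by BFGS with analytic gradient from the moment start
a₀ = mean(H), b₀ = sd(H)·√3/π, declaring convergence at gradient norm 1e−8.
Whether the original recipe accounts for the shared mixing variable is not
specified anywhere we could see; the i.i.d. fit is the natural reading of
"Hᵢ = a + b·Uᵢ" and is what is implemented.

Degenerate inputs (all depths equal, zero internal length) raise explicit
errors rather than returning infinities, so study tables can count failures.

### Sample-size domain

The pairwise estimator and the pivot are defined for n ≥ 3, but at n = 3
the denominator is a single pair and E[S₃] = ∞ (the density of |U₁ − U₂| is
positive at 0), so the Monte Carlo constants for n = 3 are unstable and the
recommended minimum is n = 4. The n = 3 row is retained in the shipped table
for completeness.

### A corrected finite-n variance

Complete covariance counting over the (n−1)(n−2) ordered pairs gives, under
the large-n law,

    Var(1/r̂) = [(n−1)(n−2)(π²/3 − 2) + 2(n−1)(n−2)(n−3)(2 − π²/6)] / ((n−1)²(n−2)² r²).

Beyond the diagonal terms (variance π²/3 − 1) and the four shared-index
classes (combined covariance contribution 2(n−1)(n−2)(n−3)(2 − π²/6)), the
count must include the reversed-pair class (k, ℓ) = (j, i): the product
(x)⁺(−x)⁺ vanishes identically, so each of its (n−1)(n−2) members contributes
covariance 0 − 1·1 = −1, turning the diagonal coefficient from π²/3 − 1 into
π²/3 − 2. At n = 4, r = 1 the variance is exactly 1/3, which the test suite
confirms by brute-force pair enumeration and 10⁶-replicate simulation. The
class is O(n²) against the O(n³) cross terms, so the asymptotic result
n·Var(r̂) → 4 − π²/3 ≈ 0.71 — also verified by simulation — is unchanged.

## Confidence intervals (`bdgrowth.confidence`)

With c = 1, P(q_lo < Sₙ < q_hi) = level gives the exact-level interval
(r̂/q_hi, r̂/q_lo) under the fixed-n law. Quantiles are empirical
(numpy's linear interpolation between order statistics) from Monte Carlo
draws of Sₙ; the shipped 0.025/0.975 pairs use 10⁶ draws, making the
quantile error O(10⁻³). The interval always uses c = 1 internally, whatever
point estimator is reported. Coverage under the exact finite-T law is not
exact but stays within Monte Carlo error of 0.95 at rT ≳ 40 (tested at
T = 40, n = 5–20).

## Trees (`bdgrowth.trees`)

Newick I/O is backed by dendropy. Validation requires branch lengths on
every edge, strictly binary nodes (polytomies are rejected, since resolving
one would fabricate coalescence times), and ultrametricity within a
configurable relative tolerance on the root-to-tip spread (default 1e−6;
reconstructed trees are only approximately ultrametric, and violations are
reported with the offending tips named). Branch lengths serialize at 17
significant digits so round trips are lossless to double precision.

The ladder (CPP) construction attaches lineage i to the nearest taller
lineage on its left, implemented iteratively with a monotone stack (O(n),
no recursion-depth limit). The tree is rooted at the sample MRCA
(deepest merge); the portion of the 0th lineage above it is kept as a stem
edge, excluded from all branch-length accounting — with that convention the
tree-traversal internal length equals the closed-form CPP expression exactly
(tested at 1e−9 over randomized orders), and the branch-length frequency
spectrum L_k (k = 1 … n−1) partitions the total length below the MRCA.
A uniform-random-merge (Harris) construction is provided as an
alternative generator of tree shapes; both constructions give the same
distribution of internal length, as the tests check by two-sample KS.

## Study harness (`bdgrowth.study`)

`run_simulation_study` applies every requested estimator to the same
simulated sample (common random numbers), counts degenerate replicates
rather than trimming outliers, and emits long-format records plus summaries
(RMSE, MAE, bias) that are exactly recomputable from the records; identical
configs produce byte-identical CSVs. `constant_sensitivity` exploits the
linearity of r̂ in c to evaluate the whole c-grid on one set of simulations.
Default replication is 1000 per scenario, matching the protocol the
estimators were originally evaluated under; the examples and tests use
200–2000 replicates with 3-standard-error (or 3-binomial-SE) tolerances.

## Problem sizes used in the checks

The test suite and acceptance script use: 10⁵ draws per inverse-CDF
KS check; 10⁶ draws for the moment identities, the c_inv(5) cross-check and
the n = 4 variance; 5000 replicates at n = 2000 for the asymptotic variance;
1000 exact finite-T replicates for coverage and for the small-sample
estimator ordering; 2000 replicates for the branch-length limits
(E[Lⁱⁿ] → (n/r)(1 − 1/(n−1)), E[L₂] → n/(2r)) at n = 10, T = 30. These sizes
make every stochastic band a 3-standard-error test of the stated value.

## Known limitations

- Exponential growth with constant, identical rates is assumed throughout;
  logistic/decelerating growth, fitness heterogeneity and spatial structure
  are out of scope (coalescence times concentrated early in the expansion
  mitigate, but do not remove, the first limitation).
- Sampling is a single time point; serially sampled (non-ultrametric) trees
  are rejected.
- The simulators generate coalescence times of the sampled genealogy only,
  not the full forward population; questions about population size
  trajectories cannot be addressed with them.
- MCMC-based and joint-likelihood (Phylofit-style) estimators are not
  implemented; comparisons are limited to the analytical estimators above.
- Synthetic data generated here are exact draws from the model being
  estimated; passing tests demonstrate correctness of the machinery and the
  calibration, not robustness to tree-reconstruction error or model
  misspecification in real data.
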