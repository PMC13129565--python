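# Methods

`cosstack` implements Bayesian inference for a latent spatial-temporal
process observed at two incompatible resolutions: noisy point-referenced,
interval-aggregated measurements (e.g., monthly means at monitoring
stations) and block-aggregated outcomes (e.g., annual county rates).  This
note records the model, the numerical choices, and what the synthetic-data
experiments do and do not establish.

## Model

A latent Gaussian process `Z(s, t)` on a planar domain and a time axis has
mean `psi(t)' gamma` (a temporal basis trend) and separable correlation

```
C((s,t),(s',t')) = C_s(|s - s'|; phi1, nu) * exp(-phi2 |t - t'|),
```

with `C_s` the isotropic Matérn and process variance `sigma2`.  Observed
quantities are averages of `Z`:

* exposure record j: `X_j = mean of Z over (site_j, interval_j) + e_j`,
  `e_j ~ N(0, delta2 sigma2 / |interval_j|)` — `delta2` is the
  noise-to-process variance ratio;
* block outcome k: `Y_k = w_k' beta1 + beta2 Z_Lk + eps_k`,
  `eps_k ~ N(0, tau2 / (|B_k| |I_k|))` — noise shrinks with the space-time
  volume of the block (an `area`-only variant is available via
  `OutcomeData(variance_form=...)`).

Covariances between averaged quantities are averages of the kernel.  The
temporal factor admits closed-form single and double integrals of
`exp(-phi2|t-t'|)` over intervals, implemented in a cancellation-free
`expm1` rearrangement of the disjoint / overlapping / nested cases (the
textbook difference-of-exponentials form loses all significant digits when
interval widths are small relative to `1/phi2`; the rearranged forms are
exact sums of non-negative terms).  Spatial integrals over polygons use
Monte-Carlo averages over a uniform within-polygon sample (default 500
points) that is **cached per polygon and reused for every matrix entry**, so
the assembled block covariance is the exact covariance of finite averages —
symmetric and PSD by construction up to the self-consistency of the sample.
Sample seeds derive from the polygon geometry, so identical polygons share
samples and duplicated supports give exactly duplicated rows.

## Inference: a cut model with conjugate modules

Inference is modular.  Module 2 (exposure) conditions only on `X`: for fixed
`(phi1, nu, phi2, delta2)` the Normal-Inverse-Gamma prior on
`(gamma, sigma2)` gives a closed-form posterior, and the latent vector at
the data supports has a Gaussian conditional with precision
`C^{-1} + D^{-1}/delta2`.  Composition sampling draws
`sigma2 -> gamma | sigma2 -> Z | gamma, sigma2`, then block- or point-level
predictions by the usual GP conditionals.  One deliberate deviation from the
obvious update formula: the conditional mean of `Z` is
`trend + M_z D^{-1} (X - trend)/delta2` — both the trend offset and the
`D^{-1}` weight are required for the draw to be the full latent process
rather than its detrended residual; the shorter form is only correct for
unit-length intervals *and* after re-adding the trend.

Module 1 (outcome) is a precision-weighted conjugate Bayesian linear
regression of `Y` on `[W, Z_L]`, refit once per posterior draw of `Z_L`.
The cut is structural: nothing in Module 2 ever sees `Y`, so outcome
misspecification cannot contaminate exposure estimates.

Block areas are rescaled to mean 1 before forming the precision weights;
raw map units would push `tau2` onto an arbitrary scale.

## Predictive stacking

Kernel decay, smoothness and the noise ratio are weakly identified, so they
are fixed on a grid of candidates (Cartesian product of per-parameter
grids; the reference design uses 3 x 3 x 3 x 2 = 54).  A helper solves for
decay values whose *effective range* (correlation = 0.05) is a chosen
fraction of the maximum inter-point distance.  Candidate posteriors are
combined with simplex weights maximising the mean leave-one-out (LOO) log
predictive density.  The optimiser is a deterministic multiplicative
(EM-style) ascent from the uniform start, polished with SLSQP when the KKT
gap has not closed; weights below 1e-8 are zeroed and renormalised.

LOO densities come in two forms:

* **exact** — each held-out observation has a location-scale t predictive
  density with `2(a_sigma + (N-1)/2)` degrees of freedom; the deleted-system
  Cholesky factors are obtained by rank-one updates of the full factor
  (O(N^3) total instead of O(N^4)), with a per-point fallback to direct
  refactorization if an update loses positivity;
* **PSIS** — importance ratios `1/N(X_j | Z_j(b), v_j(b))` over posterior
  draws, with the largest `min(0.2B, 3 sqrt(B))` ratios replaced by
  generalized-Pareto order statistics (empirical-Bayes shape/scale fit) and
  truncated at the raw maximum.  The importance density variance is the
  model's own measurement-error variance `delta2 sigma2(b)/|interval_j|`; a
  `strict_paper` mode uses the plain `sigma2(b)` instead, which contradicts
  the observation model and is kept only for comparison.  Points with Pareto
  shape k > 0.7 automatically fall back to the exact computation in the
  pipeline.

Stacked sampling draws a candidate index from the weight vector per draw and
then the requested quantity from that candidate; block-prediction machinery
(cross- and block-covariances, conditional factors) is built lazily, only
for candidates that actually receive draws.

## Confounding adjustment

Unmeasured spatial-temporal confounding in the outcome regression is
addressed by a tensor product of Gaussian radial basis functions: spatial
knots from k-means on block centroids (10 restarts, fixed seed, centroids
sorted for determinism), temporal knots evenly spaced, bandwidths fixed at
the median pairwise knot distance, evaluated at block centroids and interval
midpoints.  With a single temporal knot the temporal factor is omitted.  A
modular restricted-spatial-regression variant orthogonalises the basis
against `[W, Z_L(b)]` separately for every draw.  Basis coefficients share
the prior scale of the regression coefficients (block-diagonal extension).

## Synthetic data

The generator reproduces the structure of a monitoring-network study on the
unit square over twelve months: a daily latent field at 100 uniform sites
(360 daily steps, month = unit interval, day = 1/30), temporal mean drawn
from a GP with periodic kernel (level 5, variance 4, period 7, decay 0.1 —
the `exp(-2 lam^2 sin^2)` placement of the decay is used verbatim, with the
conventional `exp(-2 sin^2/lam^2)` selectable), unit process variance, unit
daily measurement-error variance, monthly averaging, 10% of monthly records
removed at random, and quarterly Voronoi tessellations with 40/50/30/60
cells.  Monthly values are exactly the arithmetic means of their daily
constituents.  Averaging 30 daily noise draws makes the *effective* monthly
noise ratio `delta2 = 1/30` (exposed as `SimConfig.true_kernel`) — note the
reference candidate grids place `delta2` two orders of magnitude above this,
which stacking accommodates by weight concentration.

Block-level truth is drawn from the exact conditional law of the block
average given the realised site-by-day field; the site x time Kronecker
structure reduces the conditioning to two small solves per block.  The
default truth is the noiseless latent block average; a `block_noise` switch
adds volume-scaled measurement noise.  Outcomes add an intercept, a
standard-normal confounder, an unmeasured field `g` built from an
independent draw of the same block-level kernel mixed to have correlation
`rho` with the exposure (standardised to unit variance), true coefficients
`beta1 = (1, 1)`, `beta2 = 1`, and volume-scaled noise with sd 0.5.  The
outcome coefficients and noise scale are package defaults (reported with
every run), chosen to give a signal-to-confounding ratio in which adjustment
is consequential but identification is retained.

What the generator does *not* emulate: irregular real geographies,
nonstationarity, seasonally varying missingness, shared trends between
exposure and outcome beyond the constructed confounder.  Passing tests
establish internal consistency of the machinery under the stated design,
not performance on real monitoring data.

## Numerical choices

* Matérn: half-integer orders use the exponential closed forms; other orders
  use exponentially-scaled Bessel functions assembled in log space, with the
  zero-distance limit special-cased and hard underflow floored at 0.
* Interval pairs are canonically ordered before dispatching the closed
  forms, so every exponent is non-positive; the partial-overlap orientation
  with the second interval first is handled by symmetry.
* Conditional covariances assembled from Monte-Carlo spatial averages are
  eigenvalue-clipped: eigenvalues in `(-1e-8 * lambda_max, 0)` are set to 0,
  anything more negative raises.
* `V_X` and `M_z` Cholesky failures raise errors naming the candidate; `M_z`
  retries once with a trace-scaled jitter.
* All randomness flows through `numpy` `SeedSequence` children of a master
  seed (string tags hashed with CRC32, not Python's randomised `hash`);
  reruns are bitwise identical.
* Large block-pair double averages use a fused distance+kernel loop
  (numba-compiled when available, with an equivalent vectorised fallback).

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use the full reference
data-generating design wherever a reported number depends on it (100 sites,
360 daily steps, 180 Voronoi blocks, 54 candidates), with fitting-side
choices sized for a single CPU: 100 Monte-Carlo points per polygon on the
fit side (500 on the truth side, the design value), 150–300 posterior draws
per candidate, and 2–6 replicates in the shipped scripts.  Scaled-down
geometries (20–50 sites, 2–8 quarters) are used for replicated calibration
checks.  The parameter-recovery check uses the flat IG(0.01, 0.01) variance
prior: the default IG(2, 0.1) prior contributes a visible finite-sample
shift of the variance posterior at N ≈ 160 (`E[sigma2-hat] ≈
(b + (N-r)/2)/(a + N/2 - 1)`), which is a property of the prior, not of the
likelihood machinery under test.

## Known limitations

* Exact LOO is O(N^3) per candidate and becomes the bottleneck beyond a few
  thousand observations; PSIS with exact fallback is the default.
* The Monte-Carlo spatial integrals make block covariances exact only up to
  the cached sample; very small polygons relative to the kernel range need
  fewer points, very large ones more.
* Stacking weights are not posterior model probabilities; they optimise
  one-step-ahead predictive fit and can legitimately split weight between
  kernels that predict near-identically (weak identifiability is the very
  reason for stacking).
* The outcome module assumes Gaussian errors on the (possibly transformed)
  outcome scale; count models are out of scope.
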