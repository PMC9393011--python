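# Methods

## Model

Two continuous traits evolve by correlated Brownian motion along a rooted
phylogeny whose branches are partitioned into labeled *regimes* (a painted
tree). Within regime k the process is governed by the 2×2 rate matrix
R_k = [[σ₁²ₖ, rₖσ₁ₖσ₂ₖ], [rₖσ₂ₖσ₁ₖ, σ₂²ₖ]]: σ₁²ₖ and σ₂²ₖ are
instantaneous variances (squared trait units per unit branch length) and
rₖ ∈ (−1, 1) is the evolutionary correlation. Eight nested models arise
from letting each of the three quantities be common or regime-specific
(codes 1, 2, 2b, 2c, 3, 3b, 3c, 4; see README). Each model additionally
estimates the two root states, so the parameter count is
(K or 1) + (K or 1) + (K or 1) + 2 for K regimes; any single-regime
painting collapses every model to the same 5-parameter fit.

Conditional on the painting, the tip data are exactly multivariate normal.
With trait-major stacking (all of trait 1, then all of trait 2) the
covariance is V = Σₖ R_k ⊗ C_k built blockwise, where C_k[i, j] is the
time spent in regime k on the path from the root to the most recent common
ancestor of tips i and j (to tip i itself on the diagonal). The C_k are
computed by exact postorder summation; no ultrametricity is assumed, and
Σₖ C_k always equals the single-regime structure C (a tested invariant).
The mean is D·a for root states a = (a₁, a₂).

Assumptions worth stating: species means are treated as known (no
within-species sampling error); the process is Gaussian with linear time
scaling (no stabilizing selection); regimes are given, not estimated —
uncertainty in the regime history is handled by averaging over stochastic
maps, not by joint inference.

## Likelihood and optimization

Root states enter the mean linearly, so for fixed variance parameters
their ML values are the GLS estimate â = (DᵀV⁻¹D)⁻¹DᵀV⁻¹y; they are
profiled out of every likelihood evaluation rather than searched
numerically. V is factored by Cholesky; a factorization failure (e.g. two
tips with identical root-to-tip paths) raises an explicit error — no
automatic ridge or jitter, because silent regularization would bias model
comparison. Log-likelihoods are in nats.

Free parameters are optimized in unconstrained coordinates — log σ² for
each free rate, atanh(r) for each free correlation — so every real vector
maps to a valid model and boundary handling disappears (r → ±1 maps to
infinity and is penalized naturally by the likelihood; tanh output is
clipped to 1 − 10⁻¹² to stay inside the open interval in floating point).

Starting values: the first start replicates the analytic single-regime fit
(pooled GLS cross-product of root-centered data) across regimes; further
starts jitter log rates by N(0, 1) and atanh(r) by N(0, 0.5). Each start
runs L-BFGS-B (numerical gradients), with a Nelder–Mead polish only when
the quasi-Newton pass reports failure. The quasi-Newton-first ordering was
chosen after benchmarking: on a representative 100-taxon, 3-regime
dataset it reached identical optima to a simplex-first schedule at about
one seventh of the cost, and the profiled surface is smooth in these
coordinates. Default `n_starts` is 4 for single-model fits and 2 inside
the studies.

`fit_hierarchy` fits models simplest-first and warm-starts each model from
the estimates of its directly nested sub-models (shared slots replicated).
This both speeds convergence and enforces, up to 10⁻⁶ optimizer slack, the
logical requirement that maximized log-likelihoods are monotone along the
nesting partial order 1 ≤ {2b, 2c, 3} ≤ {2, 3b, 3c} ≤ 4. A cross-check
against an independent R implementation of the same model family found
exact agreement (6 decimals) on the models where both optimizers
converged, and higher likelihoods from this package on the rest
(tests/test_reference_crosscheck.py).

Model comparison uses AIC = 2k − 2 log L and Akaike weights computed
stably (minimum subtracted before exponentiation). Rank ties break by
smaller k, then canonical code order — parsimony-consistent and
deterministic. A model that fails to fit is excluded from the weights
with a warning rather than aborting the table. Nested pairs can be tested
by the chi-square likelihood-ratio test.

## Painting conventions

- `paint_clade` puts the base→derived shift at a configurable fraction of
  the stem branch, default 0.5 (midpoint). The same default applies
  whether the derived group is a clade or a single tip.
- `paint_from_reconstruction` splits every branch whose endpoint states
  differ 50/50 at its midpoint, parent state rootward.
- Fitch/Sankoff parsimony (unit costs, valid for polytomies) supplies one
  most-parsimonious reconstruction; ambiguities resolve toward the
  parent's state (delayed-transformation flavor), and at the root toward
  the first state in sorted order. These tie rules are documented because
  "a single MP reconstruction" is otherwise underdetermined.
- The simmap dialect lists segments rootward→tipward; `segment_order=
  "tipward"` (CLI `--simmap-order tipward`) accepts the reversed
  convention, since both occur in the wild. Branch lengths are mandatory
  everywhere — the likelihood is undefined without them — and trees
  without them are rejected rather than defaulted.
- Rescaling a tree to a target height multiplies every segment; rates are
  confounded with time, so σ̂² scales inversely and ΔAIC between models is
  invariant (tested to 10⁻⁴).

## Discrete-regime machinery

Mk likelihoods use Felsenstein pruning with `expm(Q·t)` per branch
(scipy's matrix exponential; results are cached per unique branch
length). Root priors: flat by default for ER and ARD; the directional
model fixes the root at its source state — the ancestral condition the
model hypothesizes — and all three accept an explicit prior override.
`fit_mk` optimizes log rates by Nelder–Mead with a 1-D bracket polish for
single-rate structures; df is 1 (ER), s(s−1) (ARD), 1 (directional), and
AIC = 2·df − 2 log L.

Stochastic maps sample node states from their exact conditional
distributions (root from prior × partials, then preorder), and each
branch's transition path conditional on its endpoints by rejection
sampling (cap 200 tries per branch), falling back to uniformization:
jumps of a Poisson(μt) process with μ = max diagonal exit rate, jump
count drawn from its endpoint-conditioned distribution, jump chain by
backward sampling over powers of R = I + Q/μ, times as uniform order
statistics, virtual self-jumps discarded. Sampled interior-node
frequencies match pruning-based marginal posteriors within 0.03 (tested
with 2000 maps), and per-branch dwell times match the numerically
integrated conditional expectation.

## Simulators and study conditions

The simulation experiments use, as defaults: 100-taxon pure-birth trees
(birth rate 1 — pure-birth trees are scale-confounded with the rates, so
the rate is a convention); three-state equal-rates Mk regime histories
with the root state drawn uniformly, accepted only when every state is
observed in at least 20 tips (rejection cap 10⁴); generating parameters
drawn once per free slot with log σ² ~ N(0, 1) and r ~ U(−1, 1), shared
slots drawn once and replicated. This draw scheme implies a geometric
mean max/min rate ratio across three-regime draws of exp(3/√π) ≈ 5.43 and
a mean range of three correlation draws of exactly 1 — both recomputed by
the acceptance script as a check on the generator.

The Mk rate for regime histories is not pinned down by the study design;
the default is two expected transitions per unit of (realized) tree
height, a value that keeps the ≥ 20-tips rejection step acceptably rare
on 100-taxon trees while producing regime mosaics rather than a single
clade. It is exposed as `transitions_per_height` / `--rate`. Root trait
values default to (0, 0); location does not affect fit quality.

Trait simulation walks the painted tree in preorder, adding a bivariate
normal increment with covariance t·R_k per segment; the empirical tip
covariance matches the analytic V to Monte-Carlo precision (tested). All
simulators are bit-reproducible given (seed, configuration).

What the generator does *not* emulate: measurement error in species
means, extinction (no birth–death trees), non-Gaussian tail behavior, and
regime histories inferred with error. Passing recovery tests therefore
demonstrates correctness of the estimator under its own model, not
robustness to model violation.

## Study implementations and problem sizes

The model-selection study simulates, per replicate, one tree and one
accepted regime history shared by all eight generating models, then fits
all eight models to each dataset (64 fits per replicate) and tabulates
the generating model's AIC rank and the full mean-weight matrix. The
package's standing configuration for this study is 10 trees per
generating model (80 datasets, 640 fits, a few minutes on one core);
`--reps 40` reproduces the full-replication design. The recovery study
fits only the generating model and reports per-slot correlations (rates
on the log scale) and mean log-scale differences.

The stochastic-map workflow fits ER/ARD/directional Mk models, selects by
AIC, samples maps under the winner, fits the hierarchy to every map, and
orders models by rank-choice vote — lexicographic on (1st-place
frequency, 2nd-place frequency, …), a tie rule chosen here because the
vote idea alone does not determine one. Per-model parameter averages
across maps use weights proportional to each map's maximized likelihood
for that model, normalized within the model (up-weighting regime
histories that make the trait data more probable); `--flat-weights`
gives the unweighted mean, and a likelihood-weighted across-map variance
is reported as the uncertainty attributable to the discrete history.
That variance excludes within-history estimation error (no Hessian-based
standard errors are computed — out of scope).

## Numerical choices and degenerate inputs

- Segment sums are validated against branch lengths at 10⁻⁸ absolute /
  10⁻⁶ relative tolerance; zero-length branches are allowed and carry a
  single zero-duration segment.
- Newick/simmap serialization uses `repr` floats (shortest exact
  round-trip), so write∘parse preserves lengths bit-for-bit.
- Failed sub-model fits never abort a hierarchy run or a study; they are
  logged, counted, and excluded with renormalized weights.
- `akaike_weights` assigns zero weight to non-finite AICs and errors only
  if none are finite.

## Known limitations

Exactly two continuous traits (the common/different correlation
parameterization does not extend cleanly to more); Brownian motion only
(no Ornstein–Uhlenbeck); regimes must be supplied or sampled, never
jointly estimated with the trait model; the dense O(n³) likelihood is
comfortable to a few hundred taxa but is not the O(n) pruning algorithm;
no AICc/BIC, and no measurement-error inflation of the tip covariance.
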