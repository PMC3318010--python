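# Methods

This note documents the models, the numerical scheme, the synthetic-data
generators, and the design decisions behind `driftshift`.

## Phylogenetic signal (Pagel's λ under GLS)

Tip traits are modelled as multivariate normal, y ~ N(α·1, σ²·V_λ), where
V[i,j] is the branch length shared by the root-to-tip paths of tips i and j
(in Myr) and V_λ multiplies the off-diagonal entries of V by λ ∈ [0, 1].
λ = 1 is plain Brownian motion on the tree; λ = 0 makes species
independent. For fixed λ, α̂ and σ̂² have the usual closed-form GLS/ML
expressions, so λ is profiled by one-dimensional bounded optimization; the
95% support interval inverts the likelihood-ratio test (1.92 ln-unit drop).
A flat profile (no off-diagonal structure, e.g. a star tree) raises an
unidentifiability error rather than reporting an arbitrary λ̂.

The MCMC mode samples (λ, α, ln σ²) by Gaussian random-walk Metropolis
under a uniform prior on λ and flat priors on α and ln σ² (defaults:
10⁵ iterations, 10% burn-in, proposal scales tuned for ~20–40%
acceptance, explicit seed). Marginal likelihoods for the λ-free and the
forced λ=0 / λ=1 models are estimated by the harmonic mean of posterior
log-likelihoods — retained deliberately because the harmonic-mean scale is
what the Bayes-factor contrasts in this analysis tradition use, but the
estimator is high-variance and the module says so in its metadata; a
stepping-stone estimator is provided for careful work. Bayes factors are
reported on the 2·Δln scale, with ≥ 3 read as positive support.

**Deliberate exclusion:** directional drift is *not* a parameter of the GLS
stage. On an ultrametric tree a drift term shifts every tip mean by the
same amount and is therefore exactly confounded with the root state α;
drift belongs to the birth–death stage, where tree shape gives it leverage.

## Trait-dependent diversification (drift–diffusion QuaSSE-type models)

The character x (ln head–body length in mm) evolves along each lineage as
dx = θ dt + √σ² dW (θ in ln-mm/Myr, σ² in ln-mm²/Myr; θ > 0 means sizes
increase forward in time). Speciation is a function of the character —
constant c; linear max(0, a + b·x) (clamped at zero: rates are rates);
sigmoidal y0 + (y1−y0)/(1+exp(−(x−m)/r)); hump
y0 + (y1−y0)·exp(−(x−m)²/(2w²)) — and extinction μ is constant.

The likelihood uses the standard backward-time recursion on a uniform
character grid: per lineage, D(x,t) is the probability density of the
observed subtree data given the lineage is in state x at time t before the
present, and E(x,t) the probability such a lineage leaves no sampled
descendants. Tips initialize D as a Gaussian measurement density (default
sd = 1/100 of the observed trait range, floored at 1.5 grid spacings — a
narrower spike is not representable on the grid and produces spectral
ringing) and E = 0 (complete sampling of extant species). Nodes combine
daughters as D = D_left · D_right · λ_S(x). At the root, D is integrated
against weights proportional to D itself (the "observed" weighting,
default) or flat over the grid; by default the likelihood is conditioned on
survival of the two root lineages by dividing by the λ_S-weighted mean of
(1−E)². Both switches are recorded in fit metadata.

### Numerical scheme

Strang operator splitting per time step: half an exact constant-rate
birth–death update (the Riccati closed form for E and the matching
multiplicative factor for D, derived per grid point), then the
drift–diffusion step applied in Fourier space as multiplication by
exp(−σ²·h·k²/2 + i·k·θ·h) (a Gaussian blur plus an exact fractional
shift), then the second birth–death half-step. The scheme is second-order
in the step size; a dense transfer-matrix reference implementation
(`driftshift._reference`) agrees with it to < 1e-3 ln-units on two-tip
problems across a 3×3 grid of (σ², θ) values, and the trait-independent
special case factorizes into closed-form pure-birth × Brownian parts to
< 1e-3 at grid 2048.

Because all extant tips share E(·, 0) = 0, E depends only on time before
present; the implementation sweeps all lineages level-by-level from the
tips to the root on one shared step schedule, propagating E once and all
D rows as a batch (one FFT per step for the whole block). This also makes
the E vectors of sister lineages agree exactly at nodes, as the combine
contract requires.

The grid spans the observed traits padded by 5·√(σ²_max·depth) +
θ_max·depth per side, with σ²_max and θ_max the optimizer bounds, so any
admissible parameter vector keeps its probability mass in the interior;
mass reaching within one grid spacing of a boundary (> 1e-6 of the total)
raises a hard error rather than silently truncating. Default resolution:
1024 points for single analyses; the replicated simulation experiments use
128–256 points and a step of 0.02–0.03 of the tree depth (reported with
every result), a resolution at which the refinement checks above still
hold to well under 0.1 ln-unit on the relevant scales.

### Free parameters and model comparison

Every model shares one free extinction rate μ (bounded below at zero) and
the diffusion rate σ²; the speciation shape contributes 1 (constant),
2 (linear) or 4 (sigmoidal/hump) parameters; drift adds θ. The root
treatment is configuration, not a counted parameter. This accounting gives
df = 3, 4, 6, 6 for the no-drift models and 5, 7, 7 with drift, and
AIC = 2·df − 2·lnL exactly. Nested tests use χ² = 2·(lnL_model −
lnL_Full) on df_model − df_Full degrees of freedom. Fitting is bounded
L-BFGS-B from moment-based starting points (speciation scale from the
Yule rate (n−1)/total tree length, σ² from the GLS Brownian fit, θ = 0)
plus seeded jitter; `fit_battery` additionally warm-starts each model from
the best nested simpler fit, with drift launched at ±0.4·(trait
range)/depth, and falls back to the moment heuristic if every warm start
is infeasible.

Over a Bayesian tree sample, each tree is fitted independently. The
sample-level Bayes factor between two models is 2·(difference of mean
lnL across trees) — the aggregation rule is not uniquely determined by
the analysis tradition, so the per-model AIC win fraction across trees is
reported alongside as a second, assumption-free summary. Mean drift is
reported with a shortest-interval 95% HPD of the per-tree ML estimates
(ties broken toward the smaller lower bound).

## Synthetic data

`simulate_quasse_forward` runs the generating process forward in time by
first-order Euler steps (default 0.005 of the expected depth; per-step
event probabilities capped at 0.1 with automatic local refinement). When a
tip-count target is reached the process runs on to just before the next
event, so no node sits exactly at the present. The returned tree is the
reconstructed tree of extant tips (extinct lineages pruned), ultrametric
by construction. `simulate_traits` draws tip traits directly from
N(x0·1, σ²·V_λ). `simulate_alignment` is site-by-site Jukes–Cantor. All
three are byte-deterministic given a seed.

The study-scale generator defaults (`study_drift_linear_params`,
`study_constant_params`) mirror a recent small-mammal radiation: root trait
ln 90 mm, speciation ≈ 0.45/Myr at the root state rising by 0.4 per ln-mm
for the linear model, extinction 0.05/Myr, diffusion 0.08 ln-mm²/Myr,
drift +0.3 ln-mm/Myr, stopping at 100 extant tips (tree depths of a few
Myr, trait ranges of 1–3 ln-units). What these simulations do *not*
emulate about real data: incomplete species sampling, measurement error
beyond the tip-density width, rate variation among lineages beyond the
modelled trait dependence, and phylogenetic reconstruction error (the true
tree is handed to the estimator). Passing recovery tests therefore speak to
estimator correctness under the model, not to robustness against these
real-data complications.

## Drift identifiability: what the experiments show

The drift-recovery experiment (50 replicates, drift-linear, θ = +0.3,
100 tips) exposes a real and instructive limitation of the model class.
With all other parameters held at their generating values, the profile of
the likelihood over θ peaks at the true value with 2–4 ln-units of
curvature — the signal is present, carried by the interaction between the
trait-dependent speciation rate and the node-time distribution (with b > 0
and θ > 0, early lineages were smaller and speciated more slowly, so
branching accelerates through time). But when μ, b and σ² must be
estimated jointly, a near-flat ridge opens up: a higher extinction rate
mimics the same through-time acceleration ("pull of the present"), and θ
trades off against b and μ almost freely at n = 100. The joint ML
estimate of θ consequently has very large sampling variance and its median
sits well below the generating value, while μ̂ is frequently and severely
inflated — behaviour we confirmed is a property of the likelihood surface
itself, not of this implementation: the constant-rate special case of our
fits matches `ape::birthdeath` estimates to three decimals, the likelihood
is unbiased under the θ = 0 null, and the surface shape survives 8-fold
grid/step refinement. The null calibration (constant-rate data, drift vs
Full likelihood-ratio test at 2 df) holds its nominal level. The practical
reading for users: a significant drift term on real data deserves
scrutiny of the fitted μ, and single-number drift estimates from
~100-species clades should be treated as order-of-magnitude statements.

## Diagnostics

*Saturation.* Site entropy H = −Σ p·ln p over observed base frequencies;
Iss is mean site entropy divided by the full-saturation expectation,
estimated by redrawing every column iid from the overall base composition
(seeded replicates; the draw pool is sorted, so the result is invariant to
sequence order). The critical value Iss.c is calibrated in-package by Monte
Carlo: Jukes–Cantor alignments simulated on a balanced symmetric topology
over a ladder of divergences, with Iss.c the Iss at which neighbor-joining
split recovery (on JC distances) drops through 95%. This calibration is the
package's own operationalization — numerical agreement with the original
tool's published tables is not claimed — and is flagged in the result
metadata. The p-value is a one-sample t-test of per-site saturation ratios
against Iss.c.

*Node density.* n = β·x^δ is fitted to per-tip (path length, node count)
pairs by nonlinear least squares; β's significance is a permutation test
(node counts shuffled against path lengths, 1000 permutations, seeded),
acknowledging the non-independence of tips that share ancestors. Perfectly
ultrametric trees (fewer than 3 distinct path lengths) return a
not-applicable result. A sample-level wrapper reports the percentage of
trees in each (β significant) × (δ ≤ 1) cell rather than a single
ambiguous percentage.

## Known limitations

- Extinction-variable models are out of scope by design; μ is a single
  constant per fit.
- Harmonic-mean marginal likelihoods are high-variance; use the
  stepping-stone option for decisive Bayes factors.
- The tip-density floor (1.5 grid spacings) couples the effective
  measurement error to the grid resolution on coarse grids; fits intended
  for comparison must share one grid (the battery enforces this).
- The forward simulator is first-order Euler; event-time discretization is
  visible only below the default step size.
- Like every double-precision FFT implementation of this model class, the
  likelihood saturates when a tip density's true value at another tip's
  position falls below ~1e-16 of its peak (e.g. sister species whose traits
  differ by tens of conditional standard deviations): spectral noise then
  dominates the genuine tail and the computed likelihood is an
  overestimate. Data generated by the process itself never comes close to
  this regime; grossly model-violating outliers can.
- Drift estimates at ~100 tips carry the identifiability caveat above.
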