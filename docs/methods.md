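# Methods

## Model

Per-tract event counts are modeled as `y_i ~ Poisson(θ_i E_i)` with expected
counts `E_i = r h_i`, where `r = Σy/Σh` is the study-wide events-per-household
rate.  Because `Σ E_i = Σ y_i` by construction, `θ_i` is a relative risk
centred at 1 over the study region.  Tracts with zero households carry no
rate information and are excluded (with a report) before fitting.

The log relative risk contains a **neighborhood disadvantage index**
`s_i = Σ_j w_j q_ij`: a convex combination of decile scores of C
socioeconomic covariates, with simplex weights `w ~ Dirichlet(α)` estimated
jointly with everything else.  Deciles (rather than raw values) put
covariates on a common scale, damp outliers and survey noise, and loosen
collinearity.  Scores are coded 0–9, so the index ranges over [0, 9] and a
tract in the lowest decile of every variable contributes zero; β1 is then the
log relative risk per one decile-unit of the index.  (The 0–9 vs 1–10 coding
shifts only the intercept, which has a flat prior; the coding is exposed in
the scoring function's documentation and the weighted-quantile-sum
convention of 0-based scores is used.)

Covariates are **oriented** before scoring so larger values mean more
disadvantage: amount-type variables via `max(x) − x_i`, proportion-type via
`1 − x_i`.  Orientation is an explicit per-variable configuration; a helper
suggests orientations from the sign of a univariate Poisson score statistic,
but silent automation is deliberately avoided — reproducibility requires the
orientation to be part of the recorded configuration.

Four variants of increasing flexibility place unstructured exchangeable
effects `u_i ~ N(0, σ_u²)`, intrinsic-CAR spatial effects `v_i`, their sum,
or a per-tract Beta-mixed combination `a_i u_i + (1−a_i) v_i` in the linear
predictor.  Mixing is per tract by default (matching the subscripting of the
mixture formulation); a global-mixing option exists for comparison.

### Priors

* `w ~ Dirichlet(α)`, α all-ones by default (flat on the simplex; the prior
  family is fixed but its concentration is configurable).
* `β0` flat (improper); the likelihood identifies it through the offset.
* `β1 ~ Normal(m₁, σ₁²)` with `σ₁ ~ Uniform(0, 100)`.  The default prior
  mean is 0; a prior mean of 1 — unusual for a log-relative-risk
  coefficient, but in circulation for this model family — is available as a
  configuration preset (`beta1_prior_mean=1`).
* `u_i ~ N(0, σ_u²)`, `σ_u ~ Uniform(0, 100)`.
* `v | τ_v` intrinsic CAR with binary queen-contiguity weights:
  joint density `∝ exp(−(τ_v/2) Σ_{i~j} (v_i−v_j)²)`, equivalently full
  conditionals `v_i | v_−i ~ N(v̄_i, 1/(τ_v δ_i))`; `σ_v ~ Uniform(0, 100)`.
* `a_i ~ Beta(1, 1)`.

All scale parameters live on the standard-deviation scale; precisions
`τ = 1/σ²` are derived, never stored.

### ICAR identifiability

The intrinsic CAR prior is improper — invariant to adding a constant per
connected component.  Identifiability is restored by a sum-to-zero
constraint on `v` per component, enforced by recentring after every sweep.
With a single component and unit coefficient on `v` (variants 2–3) the
removed level is added to the intercept, an exact likelihood-invariant gauge
move.  In the mixture variant the coefficient `(1−a_i)` varies by tract, so
no scalar intercept shift can compensate exactly; the level is simply
dropped, the convention of standard disease-mapping MCMC software.  Because
each sweep starts from a centred field, the dropped level is numerically
tiny.  Island tracts (no neighbors) keep `v_i = 0` and are warned about at
graph construction.  The scale update for `σ_v` uses the density's proper
rank, `n` minus the number of components.

## Sampler

Adaptive random-walk Metropolis within Gibbs, one chain.  The stationary
distribution — not any particular update mechanics — defines correctness,
and every block is validated against analytic prior moments (likelihood
disabled) and an exactly integrable small posterior.

* **β0, β1**: scalar Gaussian random walks.
* **w**: per-coordinate random walk on the additive-logistic transform
  `z_j = log(w_j/w_C)`.  In z-space the Dirichlet prior times the transform
  Jacobian is `∝ exp(Σ_j α_j log w_j)`, which the acceptance ratio uses, so
  prior-only runs reproduce Dirichlet(α) exactly.  Coordinate-wise moves mix
  better than a joint proposal on a 12-simplex at negligible cost.
* **u** and **a**: element-wise parallel Metropolis (the Poisson likelihood
  factorizes over tracts given the rest, so simultaneous element-wise
  accept/reject is a valid block update); `a` moves on the logit scale with
  Jacobian correction.
* **v**: single-site Metropolis scheduled by a proper graph coloring (greedy,
  largest-first) so no two neighbors move in the same sub-block; within a
  color class neighbor sums are fixed and the prior part of each acceptance
  ratio is exactly the ICAR full conditional.  A queen lattice needs 4
  colors, so the cost is a few sparse matrix-vector products per iteration.
* **σ_u, σ_v, σ₁**: Gaussian random walks on the standard deviation,
  proposals outside (0, 100) rejected.

Proposal log-scales adapt toward acceptance 0.44 in batches of 50 iterations
with a step that decays as 1/√batch, frozen when burn-in ends, so retained
draws come from a fixed-kernel chain.  Initialization is neutral: β0 = β1 =
0, `w = α/Σα`, `u = v = 0`, `a = 0.5`, all σ = 1.  All randomness flows from
one seeded PCG64 generator and the number of draws per iteration is
data-independent, so runs are bit-reproducible across processes.

The reference protocol is 60,000 iterations with 30,000 burn-in and thinning
1 (`ModelSpec.paper_protocol()`, or `--paper-protocol` on the CLI).  Library
defaults are a lighter desk profile (6,000/2,000); validation runs in the
test suite and acceptance script use 4,000–200,000 iterations depending on
how precise the compared quantity must be — e.g. the grid-quadrature
comparison needs a long chain for sub-percent Monte-Carlo error, while DIC
ordering stabilizes quickly.  The cached linear predictor is rebuilt from
state every 500 iterations to stop floating-point drift from incremental
updates.

In prior-only runs the intercept is not updated: with the likelihood removed
its flat prior admits no stationary distribution, and the ICAR recentring
level is dropped from the linear predictor directly rather than folded into
β0 (whose accumulation would otherwise random-walk unboundedly).

Per-tract relative-risk traces are stored as float32 — a memory guard for
60,000-iteration runs at thousands of tracts (documented, and the only
quantity stored in reduced precision); scalar traces are float64.  The
mixture values' full trace is opt-in (`store_mixing_trace`) for the same
reason.

## Diagnostics

* **Geweke z**: mean of the first 10% vs last 50% of a trace, variances
  estimated by lag-windowed autocovariance sums (Bartlett window, truncation
  lag √length — the diagnostic names no estimator, so a standard spectral
  choice is documented here).  |z| < 2 is read as consistent with
  convergence.  Monitored: β0, β1, every weight, and the deviance.  With ~15
  monitored parameters an occasional |z| slightly above 2 is expected by
  chance; the CLI surfaces all of them and signals via a nonzero quality
  exit code rather than deciding for the analyst.
* **DIC**: `pD = mean(D) − D(θ̄)`, `DIC = mean(D) + pD`.  The plug-in `D(θ̄)`
  evaluates the deviance at the posterior means of every component entering
  the likelihood (β0, β1, w, u, v, a) — pD depends on this plug-in choice,
  which is why it is fixed and documented.  Deviance is −2× the full Poisson
  log-likelihood including the `log y_i!` constant; constants cancel in
  ΔDIC.  A decrease of ≥ 10 is flagged as a meaningful improvement.
* **Exceedance**: `q_ic = (1/G) Σ_g I(θ_i^(g) > c)` over post-burn-in draws,
  with defaults c = 1 and cutoff 0.90, both configurable.  No
  multiple-testing adjustment is applied (none is conventional for this
  rule).
* **Credible intervals** are equal-tailed; relative-risk parameters are
  called significant when the 95% interval excludes 1 (containment
  inclusive).
* **Moran's I** (binary weights by default, row-standardized by flag) with a
  permutation pseudo-p-value screens outcomes for spatial autocorrelation
  before modeling.

## Synthetic data

The generator emulates the anatomy of a tract-level outlet study, because
the motivating real inputs (state retailer listings, tract-level survey
estimates) are not redistributable:

* **Geography**: rows×cols unit-square lattice, queen contiguity (interior
  degree 8, edge 5, corner 3).  Default 20×20 = 400 tracts.
* **Covariates**: Gaussian copula with exchangeable correlation ρ = 0.5 by
  default (socioeconomic indicators are strongly interrelated), mapped to
  alternating Beta(2,5) proportion-like and log-normal amount-like
  marginals.  Variables are generated already oriented (identity
  orientation downstream).
* **Households**: log-normal, median 1,500, log-sd 0.5 — heavy right tail as
  in real tract systems; a scale choice, not a claim about any state.
* **Index truth**: dominant first weight 0.5 with geometrically decaying
  remainder; β1\* = 0.2 per decile-unit.
* **Rate**: r\* = 0.002 gives ≈ 3 expected events per tract (common-outlet
  regime); `sparse_rate_preset` gives ≈ 0.1 (rare-outlet regime where most
  tracts have zero events).
* **Latents**: `u* ~ N(0, σ_u*²)` with σ_u\* = 0.1; `v*` drawn exactly from
  the sum-to-zero-constrained ICAR via eigen-decomposition of the graph
  Laplacian (covariance σ_v\*² L⁺); counts Poisson at `E_i θ_i*`.
* **Missingness**: an optional per-tract probability of knocking one
  covariate cell to NaN, exercising the filter-and-report path.

Deciles of simulated covariates are produced by the same scoring code real
data take, so tie handling is exercised end to end, and the generator's
`θ*` is reproducible exactly from its stored latents through the model's own
risk formula.

What the generator does **not** emulate: survey margins of error, realistic
road-network outlet placement, irregular tract geometries, and
non-exchangeable covariate correlation.  Passing recovery tests therefore
demonstrates correctness of the inferential machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Validation design

* The sampler is checked against a **2-D grid quadrature** of the exact
  posterior on a 6-tract instance with fixed weights and random effects
  disabled (the `fixed_weights`/`fix_u_at_zero` spec hooks exist for this).
  The instance uses fixed offsets rather than data-rescaled expected counts
  so that both posterior means sit well away from zero and relative error is
  meaningful.
* **Prior-only runs** must reproduce Dirichlet component means `α_j/Σα`,
  Beta(1,1) mean 1/2 and variance 1/12, Uniform(0,100) scale mean 50, and
  the Normal prior of β1 — every block against its own analytic target.
* **ICAR algebra**: the pairwise-difference joint density must induce the
  neighbor-mean full conditional exactly at every site; the constrained
  simulator's covariance must match the Laplacian pseudo-inverse.
* **Recovery** on the 400-tract lattice: credible-interval coverage of β1\*,
  identification of the dominant weight, and rank correlation of estimated
  vs true weights.  The tiny tail weights (≤ 0.01) sit below the estimation
  floor of any finite dataset, which bounds the attainable rank correlation;
  the dominant-weight and coverage checks carry most of the evidential
  weight.
* **Hotspot calibration** elevates the relative risk to 2 on the ten tracts
  with the largest expected counts — where the offset is informative enough
  for the posterior to resolve elevation — and requires all of them flagged
  at the 0.90 cutoff with a near-zero false-flag rate among the other 90.

## Known limitations

* Single-chain inference per the reference protocol; the runner accepts
  multiple seeds for ad-hoc between-chain comparison, but no R̂ machinery is
  built in.
* Random-walk Metropolis mixes slowly for weakly identified weights; long
  runs (or the full reference protocol) are needed before weight posteriors
  settle, and the Geweke screen will say so.
* The mixture variant's recentring is the standard convention, not an exact
  gauge move (see above).
* Point-in-polygon assignment treats coordinates as planar; no projection
  handling is attempted.
* Proper-CAR reparameterizations (Leroux, BYM2) and covariate
  measurement-error models are out of scope.
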