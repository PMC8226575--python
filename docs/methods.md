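# Methods

This note documents the models, estimation procedures, numerical
choices and known limitations of `countcast`.

## Models

### Linear conditional-intensity model (INGARCH / MACI)

Counts are conditionally Poisson given the past,
`X_{i,t} | F_{t-1} ~ Poisson(λ_{i,t})`, with the intensity vector
following the linear recursion

    λ_t = ω + A λ_{t-1} + B X_{t-1},

all coefficients non-negative so the intensity stays positive.
`‖A + B‖₂ < 1` is the sufficient stationarity condition checked by
`maci.check_stationarity`; the unconditional mean is
`(I − A − B)^{-1} ω`.  One lag of each term is supported — the standard
operative form of the model — and cross-series dependence enters through
the off-diagonal entries of `A` and `B`, which are restricted to be
non-negative; contemporaneous dependence, when requested, is added by a
common Poisson shock (below).

### Log-linear count autoregression

The log-intensity `ν_t = log λ_t` follows

    ν_t = ω + A ν_{t-1} + B log(X_{t-1} + 1),

with unrestricted real coefficients — the log link guarantees a positive
intensity, so negative own- and cross-feedback are representable, which
the linear model excludes by construction.  The `+1` offset makes the
feedback term vanish on zero counts.  Stability is monitored through the
partial sums of `Σ_j ‖A^j B‖₂` with a geometric tail bound when
`‖A‖₂ < 1`; the condition `Σ_j ‖A^j B‖₂ < 1` guarantees stationarity and
weak dependence.

### Poisson state-space model

A parameter-driven alternative: a latent Gaussian VAR drives the
intensity nonlinearly,

    X_{i,t} ~ Poisson(λ_{i,t}),   λ_t = β ⊙ exp(h_t),
    h_t = Φ₁ h_{t-1} + … + Φ_p h_{t-p} + η_t,   η_t ~ N(0, Σ_η).

Stationarity is the usual VAR condition, checked via companion-matrix
eigenvalues.  Off-diagonal `Φ` entries encode (signed) Granger-causal
feedback between the latent intensities; the innovation correlation
encodes signed contemporaneous dependence.  In the bivariate case
`Σ_η` is parameterized as `(σ₁, σ₂, ρ)` with covariance `ρσ₁σ₂`.
Conditional on the latent path the counts are independent over time and
across series.

### Multivariate Poisson constructions

Contemporaneous positive dependence for the observation-driven models is
built from independent Poisson shocks:

* **common shock** — `X_i = Y_i + Y_0` with `Y_0 ~ Poisson(λ₀)` shared by
  all series; every pairwise covariance equals `λ₀`, so the construction
  is simple but equicovariant, and only positive dependence is possible.
* **pairwise shock** — one shared component per pair `(i,j)` with
  intensity `λ_ij`; the covariance matrix has the `λ_ij` off the
  diagonal and the (equi-dispersed) means on it.

Joint pmfs are evaluated in log space with log-gamma factorials — the
shock sums run through the observed counts and overflow in natural
scale.  The n-variate common-shock pmf is evaluated in the binomial-sum
form with prefactor `exp(-λ₀ - Σλ_i)` and an `(i!)^{n-1}` term, which is
the correct generalization of the bivariate formula (verified against
the direct convolution in the tests).  No closed pmf is attempted for
the pairwise-shock construction beyond n = 2 — it is supported through
its moments and its sampler.

## Estimation

### Quasi-maximum likelihood (observation-driven models)

Both observation-driven models are fitted by maximizing the Poisson
quasi-log-likelihood `Σ_t Σ_i (x_{i,t} log λ_{i,t} − λ_{i,t})` (the
factorial term is constant in θ and dropped).  The score, observed
information `H_T` and conditional information `G_T` are computed by
exact derivative recursions of the intensity path, including the full
second-derivative tensor for `H_T` — no numerical differentiation is
used anywhere in fitting.  `H_T` follows the sign convention of a
negative Hessian (positive definite near a regular optimum), and the
reported standard errors are the sandwich `H⁻¹ G H⁻¹`, valid under a
correctly specified conditional mean even when the counts are not truly
Poisson.  `G_T` uses the working-Poisson substitution of the conditional
count covariance by `D_t = diag(λ_t)`.

Parameter packing is `θ = [ω, vec(A), vec(B)]` (column-major), giving
dimension `d = n(1 + 2n)`.

Numerical choices:

* The intensity recursion is initialized at the per-series sample mean
  (log mean for the log-linear model), held fixed during optimization so
  the analytic gradient is exact; derivative recursions start at zero.
  Initialization effects decay geometrically in the stationary region.
  Forecast and filter methods of a fitted model reuse the same
  initialization for consistency with the estimated likelihood.
* Simulation initializes the intensity at the unconditional mean when
  the process is stationary (ω, i.e. ν₁ = ω, for the log-linear model),
  so simulated paths start in approximate stationarity without burn-in.
* Linear model: L-BFGS-B on the positive orthant with lower bound 1e-8;
  coefficients pinned at the bound are flagged, since boundary inference
  is unreliable (no bootstrap correction is attempted).  Starting values
  come from per-series univariate fits, cross terms seeded at 1e-3.
* Log-linear model: unconstrained L-BFGS-B with 5 starts by default
  (univariate-fit seed plus Gaussian perturbations of scale 0.1); the
  best quasi-likelihood wins, ties broken by the smallest parameter
  norm.  Parameter regions whose filtered path exceeds ν = 30
  (λ ≈ 10¹³) are penalized during the search and raise a guarded
  explosive-path error elsewhere; unrestricted coefficients genuinely
  admit explosive dynamics and small-sample fits can be unstable.
* Optimizer tolerances are tightened (ftol 1e-12, gtol 1e-7) so the
  score at the reported optimum is small relative to the sample size.

### Particle filtering and particle MCMC (state-space model)

The likelihood of the state-space model is an intractable integral over
latent paths; it is estimated by a bootstrap particle filter: particles
propagate through the VAR transition, are weighted by the Poisson
observation density, and are resampled systematically every step.  The
per-step likelihood increment is the log of the mean unnormalized
weight, accumulated by log-sum-exp — the standard unbiased estimator
that particle MCMC requires.  All weights are handled in log space; a
filter whose maximum log-weight underflows raises a degeneracy error
naming the time step.  Initial particles are drawn from the stationary
VAR distribution (discrete Lyapunov solve).  The default Poisson /
VAR(1) / systematic path has a numba-compiled inner loop that follows
the exact draw order of the numpy path, so both produce identical
output for the same seed.

Smoothing uses forward-filtering backward-sampling: trajectories are
drawn backwards by reweighting filtered particles with the VAR
transition density (O(NT) per path); marginal smoothing weights via the
full backward recursion (O(N²T)) are also available.  Both are validated
against exact Kalman filter/smoother results on a linear-Gaussian
analogue (same latent VAR, Gaussian measurement) in the test suite.

Posterior inference is by particle marginal Metropolis-Hastings on the
transformed parameter vector `(log β, Φ, log σ, atanh ρ)`:

* Priors (weakly informative, proper): `log β_i ~ N(0, 10)`,
  `Φ_ij ~ N(0, 1)` truncated to the stationary region by default,
  `log σ_i ~ N(0, 1)`, `atanh ρ ~ N(0, 1)`.
* Proposal: joint Gaussian random walk.  During warm-up the global step
  size follows Robbins-Monro toward 30% acceptance (inside the 25-40%
  target band) and, after the first 200 iterations, the proposal shape
  is refreshed every 50 iterations from the empirical covariance of the
  chain history (adaptive-Metropolis, factor 2.38/√d).  Both freeze at
  the end of warm-up, so the retained chain is a valid Markov chain.
* The current state's likelihood estimate is stored and never
  recomputed, preserving the exact-approximation property.
* A proposal whose filter degenerates is rejected with a warning, not a
  crash; proposals outside the prior support skip the filter entirely.

Posterior summaries report mean, median, kernel-density mode (Gaussian
KDE, Silverman bandwidth, maximized on a 512-point grid) and
highest-posterior-density bounds (shortest interval containing the
requested mass, computed from sorted draws).

## Forecasting

Forecasts condition on data through the origin T only; the posterior is
not re-estimated between horizons.  For the state-space model each
predictive replicate samples a posterior parameter draw and a terminal
filtered particle (by weight), propagates the latent VAR s steps and
emits Poisson counts — parameter and state uncertainty both enter the
predictive.  The terminal particle set is produced by one filter run at
the posterior-mean parameters; mixing over per-draw filter runs would
cost a full filter per retained draw for a second-order refinement of
the state distribution.  For the observation-driven models the one-step
predictive is exact (the intensity is a deterministic function of the
data) and multi-step predictives are generated by stochastic path
simulation, feeding sampled counts back into the recursion, so a full
predictive distribution is available to every scoring rule.

Predictive pmfs are Rao-Blackwellized Poisson mixtures over the
replicate intensities when available (empirical frequencies otherwise),
on a support extended to the 1 − 1e-9 quantile of the fitted mixture.

## Scoring

Six negatively oriented rules: logarithmic `−log p_x`, quadratic
`−2p_x + ‖p‖²`, spherical `−p_x/‖p‖`, ranked probability
`Σ_k (P(X≤k) − 1(x≤k))²`, squared error `(x − μ_p)²`, and
Dawid-Sebastiani `((x−μ)/σ)² + 2 log σ`.  Literal variants with the RPS
indicator reversed to `1(x≥k)` and the DSS square dropped are available
behind `as_printed` flags for comparison with sources that print those
(non-proper) forms.  Multivariate forecasts are scored per series and
horizon on the marginal predictives and averaged; MSE/MAE of the
predictive-mean point forecast are also reported.  Truncation of the
support changes every score by less than 1e-8 once the omitted tail
mass is below 1e-12 (verified by doubling-support tests).

## Synthetic-data generators and the benchmark

The DGP catalog pins five named bivariate settings used throughout the
tests and the benchmark: three state-space DGPs sharing β = (1, 2),
triangular Φ with diagonal 0.5 and φ₂₁ = 0.3 (series 1 Granger-causes
series 2, not vice versa), innovation scales 0.5, and innovation
correlation ρ = +0.3 / −0.3 / 0 (SSM1/SSM2/SSM3); and two log-linear
DGPs, LL1 with negative own-feedback a₁₁ = −0.5 and LL2 all-positive
(ω = (0.2, 0.3), a = (0.2, 0.4), b₁₁ = 0.5, b₁₂ = 0.2, b₂₁ = 0,
b₂₂ = 0.4).  These generators emulate stationary, low-count, cross-
correlated surveillance-style series.  They do not emulate covariates,
seasonality, structural breaks, over-dispersion beyond what the latent
process induces, or the heavy spikes seen in, e.g., high-frequency
transaction counts — so passing tests demonstrate correctness of the
machinery and qualitative model-comparison behaviour, not performance
on such data.

The benchmark driver simulates each DGP, fits the log-linear model by
QML and the state-space model by PMMH on the training window, forecasts
the held-out horizon, scores all six rules, and averages over
replicates (replicate seeds are base + index).  A replicate whose fit
fails is recorded and excluded, not fatal.

### Run scales

Full-scale posterior settings (N = 5000 particles, M = 20000 iterations,
5000 warm-up) are available behind `scale="full"` but cost hours.  The
package's reduced-scale defaults, used by the test suite and the
acceptance script, were chosen once as the smallest sizes at which the
MCMC output is usable:

* parameter-recovery checks: T = 200, N = 500, M = 6000, warm-up 2000;
* directional benchmark: T = 160, horizon 5, N = 250, M = 1500,
  warm-up 500, with majority votes over replicates;
* QML recovery: T = 2000, single-start fits seeded from univariate
  estimates.

At these scales the qualitative conclusions (which model family wins on
which DGP; coverage of well-identified parameters) are stable across
seeds; exact score values are not comparable across scales.

## Known limitations

* The innovation correlation ρ of the state-space model is weakly
  identified in short series (T ≲ 200) at low intensities: the
  posterior is wide and slow-mixing, and its HPD interval can exclude
  the generating value on individual datasets.  Long chains with
  adaptive proposals mitigate but do not remove this.
* PMMH inference is implemented for the VAR(1) latent process (the
  practically estimable case); higher lag orders are supported in
  simulation, filtering and stationarity checking only.
* Only positive contemporaneous dependence is available to the
  observation-driven models (shock constructions); signed dependence
  requires the state-space model.
* Missing values are not supported anywhere; series must be complete.
* The bootstrap filter proposes blindly from the transition, so very
  sharp observations (large counts under a diffuse latent state) can
  degrade it; look-ahead proposals are not implemented.
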