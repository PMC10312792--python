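# Methods

This note records what `elatools` computes, the numerical choices made, and
their rationale.  Symbols: N channels (ROIs), t_max time points, σᵢ ∈ {−1, +1}.

## Preprocessing

`zscore_global` standardizes each time point *across channels*:
z_it = (x_it − m_t)/s_t with m_t, s_t the mean and standard deviation over
channels at time t.  This removes any signal common to all channels at a
given time (a global signal) exactly.  The default uses the population
standard deviation (`ddof=0`); `ddof=1` is available.  A time point where
all channels are equal has s_t = 0 and raises an error naming the time
index.

`binarize` thresholds each channel at its own time mean: σ_it = +1 if
z_it > mean_t(z_i), else −1 (ties map to −1, so a constant channel becomes
all −1).

## Pairwise maximum-entropy model

E(V) = −Σᵢ hᵢσᵢ − ½ ΣᵢΣⱼ Jᵢⱼσᵢσⱼ with J symmetric, zero diagonal;
P(V) ∝ exp(−E(V)).  All model quantities are computed by exact enumeration
of the 2^N states; `MAX_ENUM_N = 15` bounds memory and time (a 2^15-state
table is ~1 MB; each fitting iteration is O(2^N · N²)).  States are encoded
little-endian: bit i of the state index is channel i, bit 0 → channel 0,
bit value 1 → σ = +1.

### Likelihood maximization

Iterative moment matching (gradient ascent on log-likelihood): the
classical update adds ε·log(⟨σ⟩/⟨σ⟩_m) to each parameter, which is
undefined when a ±1-coded moment is zero or negative.  The default
`multiplicative` mode applies the identical log-ratio update to
probability-scale moments p = (⟨σ⟩+1)/2 ∈ (0, 1); it has the same fixed
point (model moments = data moments, the unique maximum-likelihood
solution) and is defined everywhere.  An `additive` mode
(h ← h + ε(⟨σ⟩ − ⟨σ⟩_m)) is also provided.

Defaults: ε = 0.2, tolerance 10⁻⁶ on the maximum absolute probability-scale
moment error, max 500 000 iterations, h = J = 0 initialization.  Empirical
probabilities are clipped to [1/(2·t_max), 1 − 1/(2·t_max)] (a half-count)
so that saturated moments (|⟨σ⟩| = 1) remain attainable; a warning is
issued when clipping occurs.  Non-convergence is reported on the returned
`FitResult`, and estimators built on top raise rather than accept a
non-converged fit.  Near-frozen data (sampled |⟨σᵢσⱼ⟩| ≈ 1, i.e. strong
couplings and short series) make the likelihood maximum drift toward the
clipped target and convergence can stall; this is an intrinsic regime
limit of single-session fitting, not a tolerance issue.

### Accuracy index

r_D = (D₁ − D₂)/D₁ with D_ℓ the Kullback–Leibler divergence (base-2 logs,
0·log 0 = 0) from the empirical pattern distribution to the ℓ-th-order
model.  r_D = 1 when the pairwise model reproduces the data exactly; r_D = 0
when it adds nothing over the independent model (e.g. the N = 3 parity
distribution, which has only third-order structure); NaN when D₁ = 0.

### Variational Bayes across sessions

For D sessions sharing a participant, parameters θ_n ∈ R^M
(M = N(N+1)/2, ordered h₁…h_N, J₁₂, J₁₃, …) get a factorized Gaussian
posterior q_n = 𝒩(μ_n, diag(1/β_n)) under a shared prior 𝒩(η, diag(1/α)).
Each outer iteration updates every session by a Laplace-style step around
the prior mean —

  μ_n = η + t_max·A⁻¹(⟨σ̄_n⟩ − ⟨σ̄⟩_η),  A = diag(α) + t_max·C_η,
  β_n = α + t_max·c_η,

with ⟨σ̄⟩_η and C_η the exact model mean and covariance of the M feature
functions at η, c_η its diagonal (solved by Cholesky factorization) — and
then re-estimates the prior empirically: η = mean_n μ_n,
α = 1/mean_n[(μ_n − η)² + 1/β_n].

Initialization: η ~ 𝒩(0, 0.1²) (seeded), α = 6 for bias entries and 30 for
coupling entries (couplings are expected to be smaller and more numerous).
Convergence: |ELBO(t)/ELBO(t−1) − 1| < 10⁻⁸.  The ELBO uses a second-order
expansion of log Z around each posterior mean (exact Gaussian
cross-entropy of the quadratic term) plus the exact Gaussian
prior–posterior KL; it is monotone in practice and serves as the stopping
statistic.  `MAX_VB_N = 12` bounds the exact M-feature covariance
computation (O(2^N · M²)).

## Energy landscape

- **Local minima**: states strictly lower in energy than all N single-flip
  neighbors, reported in ascending energy order.
- **Threshold energy Eth(γ, γ′)**: the smallest energy ceiling at which the
  two minima are connected in the subgraph of states with energy ≤ ceiling;
  computed by inserting states in ascending energy into a disjoint-set
  structure.  This equals the minimax path value and is an ultrametric,
  giving a well-defined merge tree (disconnectivity graph).
- **Branch length** of minimum γ: min over other minima of Eth − E(γ);
  defined as 0 when only one minimum exists.
- **Pruning**: minor minima whose branch length is indistinguishable from
  chance are removed iteratively (shortest branch first, global minimum
  protected).  The chance threshold is μ′ + 2σ′ over the mean branch
  lengths of landscapes fitted to 100 random fair-coin series of the
  estimation length (4·t_max when four sessions are concatenated,
  `length_multiplier=1` otherwise).
- **Basins**: steepest descent (move to the lowest-energy strictly lower
  neighbor; ties broken toward the smallest channel index) iterated to a
  fixed point assigns every state to a minimum.  States whose minima were
  pruned are absorbed into the surviving minimum with the lowest barrier.

## Discrepancy measures between two landscapes

With m₁ ≤ m₂ the two minima counts (inputs swapped if needed):

- **dJ** = (2/(N(N−1))) Σ_{i<j} |J⁽¹⁾ᵢⱼ − J⁽²⁾ᵢⱼ|.
- **dH**: minimum over all m₂!/(m₂−m₁)! injective matchings of the mean
  Hamming distance between matched minima patterns.  Matchings are
  enumerated exhaustively when their count is ≤ 10⁶ (ties broken toward
  the lexicographically smallest matching); otherwise the equivalent
  linear-sum-assignment solver is used.
- **dbasin**: same minimum-matching construction on cosine distances
  1 − cos∠(u⁽¹⁾, u⁽²⁾) between basin-average activity vectors
  (uᵧ = mean of all patterns in basin γ); range [0, 2], maximum 2 attained
  by anti-aligned vectors.
- **dL** = |L₁ − L₂|/max(L₁, L₂) on mean branch lengths, defined as 0 when
  both are 0.

## Reliability: ND = d2/d1 permutation test

Given a complete participants × sessions grid:

- **Pairwise design**: fit each cell separately; d1 averages the chosen
  measure over all P·S(S−1)/2 within-participant session pairs, d2 over
  all S·P(P−1)/2 same-session participant pairs.
- **Concatenated design** (likelihood-max only): per participant, 10 random
  draws of two disjoint m = 4-session sets feed d1; per session, 10 random
  half/half participant splits feed d2.

ND = d2/d1; values > 1 indicate individual-specific structure.  The
permutation test recomputes ND on c reshuffled grids (`global`: all cells
permuted; `within_session`: participants permuted within each session
column) and reports the fraction of null NDs *strictly greater* than the
observed value.  Replicates with d1 = 0 are excluded and counted; a zero
exceedance count is reported as "p < 1/c".

Because each fitted cell (or concatenation, keyed by its sorted cell set)
is a deterministic function of its data, estimates are memoized: a
permutation replicate only re-indexes cached fits, which makes c in the
hundreds or thousands cheap.  Chance-level pruning statistics are cached
per (N, estimation length).

## Synthetic cohorts

Generating parameters: θ_ps = θ_base + δ_p + δ_ps with
δ_p ~ 𝒩(0, participant_sd²) and δ_ps ~ 𝒩(0, session_sd²) applied
independently to every h and upper-triangular J entry.  Sampling is exact
(inverse-CDF over the 2^N Boltzmann probabilities, i.i.d. across time); a
Glauber-dynamics sampler is available when temporally correlated samples
are wanted.  `default_base_params` draws h ~ 𝒩(0, 0.1²) and
J ~ 𝒩(0, 0.3²) — weak fields with moderate couplings, producing multiple
minima at N = 5–8 without freezing.  Continuous cohorts add a shared global
signal g_t ~ 𝒩(0, 1) and i.i.d. noise to the ±1 latent states, exercising
the full preprocessing path.  All randomness flows from
`numpy.random.SeedSequence` spawns, so every artifact is reproducible from
a single integer seed.

## Scope and limitations

- Exact enumeration bounds: N ≤ 15 (likelihood-max, landscapes), N ≤ 12
  (variational Bayes).  Larger systems need sampling-based estimators that
  are out of scope here.
- The model assumes stationarity within a session and exchangeable time
  points; temporal autocorrelation in real recordings effectively reduces
  the number of independent samples.
- The synthetic generator perturbs parameters with i.i.d. Gaussians; it
  does not model structured group differences, scanner effects, or
  heavy-tailed individual variation.
- p-values are permutation-based and hence granular at 1/c; they test
  exchangeability of cells under the chosen shuffle, not any parametric
  null.
- The variational posterior is factorized (diagonal covariance) and its
  update is a single Laplace-style step per outer iteration; for strongly
  coupled systems the posterior correlations it ignores may matter.
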