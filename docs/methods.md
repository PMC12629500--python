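# Methods

## Model

The all-or-none-conductance-based (AONCB) neuron integrates excitatory and
inhibitory conductance transients between the reversal potentials
V_i < V_L = 0 < V_e with passive time constant τ = C/G.  Synapses activate
all-or-none for a duration τ_s; the instantaneous-synapse limit ε = τ_s/τ → 0
is taken at fixed dimensionless weight w = g τ_s/C, so that each synaptic
event transfers a fixed charge.  In that limit the drive is the derivative
of a compound Poisson process: events at Poisson rate b with i.i.d. jumps
(W_e, W_i) = (Σ_k w_{e,k} X_{e,k}, Σ_l w_{i,l} X_{i,l}), where the binary
activation variables X encode which inputs coactivate.  Synchrony is fully
specified by the joint activation law; the framework represents nonnegative
spiking correlations only.

The correct interpretation of the multiplicative (state-dependent) jumps is
the Marcus one, obtained as the vanishing-regularization limit of the
finite-τ_s dynamics: at an event the voltage moves toward the mixed reversal
(W_e V_e + W_i V_i)/(W_e + W_i) by the fraction 1 − e^{−(W_e+W_i)}.  This
keeps the voltage inside (V_i, V_e) for zero injected current and makes the
trajectory piecewise exponential — and hence exactly simulable event by
event.

## Spiking correlations

Binned at resolution dt → 0, the Pearson correlation of two inputs'
spike-count indicators reduces to ρ_{kl} = E[X_k X_l]/√(E[X_k] E[X_l]) over
the per-event activation law; order-n coefficients use the n-th root of the
product of marginals.  These are the quantities the package computes,
because they are the only dimensionally consistent dt → 0 limits: in
particular b·E[X_k X_l] = ρ_{kl} √(r_k r_l) (with the individual rates
r_k = b·E[X_k]), which is what all small-weight quadratic forms use.  For
the exchangeable beta-binomial pool (pairwise correlation ρ = 1/(1+β)) the
event-size distribution is p(k) ∝ C(K,k) B(k, K−k+β) with collective event
rate b = r β (ψ(K+β) − ψ(β)); this form is fixed by the two pinning
properties r_{K=1} = r and b ~ β r ln K, and equals the normalization sum of
the event pmf.  The order-3 coefficient of this model is 2ρ²/(1+ρ),
consistent with the general product formula ∏_{k<n} k/(β+k) and verified by
direct enumeration.

## Exact stationary moments (PASTA)

Because the stationary law just before a Poisson event equals the
time-stationary law, writing one Marcus update plus one exponential waiting
time between two consecutive event times turns stationarity into a linear
fixed-point equation per mixed moment.  For a multiset A_n of neuron labels
with multiplicities m_a,

    μ_m ( Σ_a m_a/τ_a + b E[1 − Π_a Y_a^{m_a}] )
      = b Σ_{j<m} Π_a C(m_a, j_a) μ_j E[ Π_a Y_a^{j_a} (R'_a (1−Y_a))^{m_a−j_a} ],

with Y_a = e^{−(W_{e,a}+W_{i,a})}, R'_a the mixed reversal shifted by the
resting level, and μ_∅ = 1.  The system is triangular in the total order and
solved bottom-up; centered moments follow by binomial expansion around the
means.  R' is set to 0 on zero-jump atoms, where its prefactor (1−Y)
vanishes, and the recursion is invariant under adding null events, so a
population-level jump model can be reused unchanged for any sub-multiset.
Orders up to 6 are cheap; the sub-multiset lattice grows combinatorially
beyond that.

Expectations over jumps run through three backends selected by the model
representation: exact atom enumeration, exact summation over the
beta-binomial event pmf (also an atom model, one atom per event size), and
seeded Monte Carlo with a reported standard error for sampler-only models.

## Closed forms and small-weight approximations

The engine reproduces, and is tested to 1e-10 against, the compact closed
forms: the stationary mean through the rate coefficients
c_α = b E[W_α/(W_e+W_i) (1−Y)], the pair covariance
M_12 = b_12 E[R_1(1−Y_1) R_2(1−Y_2)] / (1/τ_1 + 1/τ_2 + b_12 E[1−Y_1Y_2]),
and the third-moment form
M_3 = b (E[R³(1−Y)³] + 3 M_2 E[R(Y²−1)(1−Y)]) / (3/τ + b E[1−Y³]).

Taylor-expanding the exponentials for w ≪ 1 gives the interpretable
formulas: variance and covariance as driving-force quadratic forms over an
effective time constant, the uniform-pool amplification factor 1 + (K−1)ρ,
the excitatory variability share q, the shared-input correlation
ρ_V = f_e q + f_i (1−q), and the synchrony correlation
ρ_V = ρ′/((1−ρ)/κ + ρ) with κ = M|_{ρ=1}/M|_{ρ=0}.  For uniformly
cross-correlated excitation and inhibition the fully synchronous event is a
joint e+i activation whose driving forces partially cancel, giving
κ = (√(K_e q) − √(K_i(1−q)))²; this reproduces the reference checks
κ ≈ 0.6 K_e at rest (we obtain 0.625) and ≈ 0.08 K_e at 15 mV
depolarization (we obtain 0.088).

The excitation-only skewness approximation is implemented as

    S[V] ≃ s[V] · (1 − 2 c_e τ)/(1 + c_e τ) · √(1 + ρ_e K_e),
    s[V] = 2√2 / (3 √(K_e r_e τ)),

with c_e = K_e r_e w_e the total excitatory rate coefficient.  At the
biophysical operating point K_e w_e = 1 the drive factor is the familiar
(1 − 2 r_e τ)/(1 + r_e τ) with its sign change at r_e = 1/(2τ) ≈ 33 Hz; the
c_e form was chosen because it tracks the exact engine away from that
operating point and is exactly invariant under failure compensation (below).
The √(1 + ρ_e K_e) amplification is a weak-synchrony approximation: for
ρ_e K_e ≫ 1 the exact engine gives a stronger gain (≈ 2√(ρK)), so the
approximate route is quoted only where ρ_e K_e ≲ 30 and the exact
third-moment engine is the ground truth otherwise.  The worked values
(s[V] ≈ 0.24 and 0.049 at r_e = 1 and 25 Hz; S[V] ≈ 0.23 and 1.30 at
ρ_e = 0 and 0.03) correspond to the moderate cortical weight w_e = 10⁻³
with K_e = 10³, i.e. K_e r_e τ = 15.

## Input generation

Correlated rasters use binomial mixing: per dt-bin (default 10⁻⁴ s), each
homogeneous subpopulation draws θ_i ~ Beta(α_i, β_i) with
α_i = r_i dt (1/ρ_ii − 1), β_i = (1 − r_i dt)(1/ρ_ii − 1) (mean exactly
r_i dt, within-block pairwise correlation ρ_ii exactly under the shared-θ
construction), then counts k_i ~ Bin(K_i, θ_i).  Cross-block dependence
enters through a Gaussian copula whose correlation matrix is calibrated pair
by pair (Brent root finding on the Gauss–Hermite quadrature of the bivariate
moment, cached per parameter tuple, tolerance 1e-10) to the target

    E[θ_i θ_j] = r_i r_j dt² + ρ_ij √(r_i r_j) dt,

the dt → 0 limit of the binned Pearson correlation; infeasible targets
(beyond the comonotone moment) and non-PSD assembled matrices raise
immediately.  ρ → 0 falls back to independent thinning and ρ → 1 to a
shared Bernoulli mixer, where the beta parameters degenerate.  A single
seed spawns independent substreams for the copula and binomial draws.

All spikes in one bin form one synaptic event at the bin's right edge —
that is the synchrony semantics.  Jittering shifts each spike by an
independent N(0, σ_J²) and wraps times periodically into [0, T); the wrap
preserves marginal rates and stationarity exactly (boundary handling is our
choice; reflecting or discarding would bias edge rates).  Instantaneous
ρ = 0.25 with σ_J = 50 ms measures ≈ 0.033–0.035 in 25 ms windows at
T = 200 s in this implementation, against a nominal reference of 0.03.

## Simulators

The event-driven simulator applies the affine per-event recursion
u_n = e^{−Δt_n/τ − W_n} u_{n−1} + R̃_n (1 − Y_n) via blocked cumulative
products (blocks capped at 250 log-decades to avoid under/overflow), which
is exact and vectorizes to ~10⁷ events per second.  The finite-τ_s
reference integrator opens a box-car conductance of amplitude W τ/τ_s per
event and advances with forward Euler (dt_euler < τ_s enforced); it exists
to validate the ε → 0 limit: at ε = 0.0013 the stationary mean and variance
match the Marcus simulator within 2% on matched drive, and the
Kolmogorov–Smirnov distance of the stationary samples decreases with ε.

Gap-junction pairs (dimensionless coupling g = G_12/G, identical τ) use the
exact inter-event propagator in the symmetric/antisymmetric eigenbasis
(decay rates 1/τ and (1+2g)/τ) with unchanged per-neuron Marcus updates.
The first-moment balance gives coupled means as weighted averages of the
uncoupled ones, m_1 = [A_1A_2 m_1⁰ + (g/τ)(A_1 m_1⁰ + A_2 m_2⁰)] /
[A_1A_2 + (g/τ)(A_1+A_2)] with A_a = 1/τ + c_a, which recovers the
uncoupled means at g = 0 and a common A-weighted mean as g → ∞; both limits
and intermediate couplings are validated against the exact pair simulator.

## Empirical estimation

Traces are piecewise exponential, so time integrals of voltage products are
exact sums over inter-event segments, (1 − e^{−sΔ})/s per segment with
s = Σ_a 1/τ_a (for coupled pairs, the product is expanded in eigenmode
powers, each with its own rate).  The final partial interval is included
with T_{N+1} = T.  Defaults: burn-in 20 τ before collecting statistics,
block-bootstrap block length 100 τ (both configurable); the bootstrap
resamples contiguous blocks and recomputes every derived statistic, so
standard errors propagate through centering.  Over 100 seeded replicates
the estimators are unbiased within two standard errors of the mean for
orders 1–3 and 95% bootstrap intervals cover the exact values at a rate
within [88%, 99%].

## What the synthetic data does and does not emulate

The generator reproduces stationary, instantaneously (or jitter-spread)
synchronous input with block-uniform correlations and binomially mixed
counts.  It does not emulate temporally structured rate fluctuations
(Cox-process synchrony with intrinsic timescales), negative correlations
(excluded by the jump construction), refractoriness, or non-stationary
drive — so passing tests certify the theory–simulation loop under the
model's own assumptions, not the full statistics of in-vivo spike trains.

## Scales and runtimes

Test and validation runs use simulated durations of 10²–10³ s (10⁵–10⁶
events per model; the randomized simulator-vs-theory suite uses 20 models
at ≥10⁶ events each), chosen so the whole suite completes in well under a
minute on one core while keeping Monte Carlo standard errors at the few
per-mil level.  Experiment runners default to T = 100 s per grid point with
a `--full` flag for figure-scale durations.

## Known limitations

- Negative or temporally structured input correlations are out of scope.
- The small-weight skewness amplification underestimates strong synchrony;
  use the exact engine there.
- Failure compensation (K′ = K/p at fixed weights) restores the mean
  exactly but the variance only to leading order in 1/K: the synchrony
  factor becomes 1 + (K−p)ρ instead of 1 + (K−1)ρ, a relative residual
  (1−p)ρ/(1+(K−1)ρ) (~10⁻⁴ at cortical parameters).
- Gap-junction closed forms and the exact pair propagator assume identical
  membrane time constants; heterogeneous-τ pairs would need the generic
  matrix exponential.
- No spiking mechanism: all statistics are subthreshold by construction.
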