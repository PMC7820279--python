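# Methods

## Model and assumptions

The probe is a sphere of radius *a* (default 1.95 µm) in a harmonic trap of
stiffness *k*, immersed in a Jeffreys fluid: a Newtonian solvent (viscosity
η₀) in parallel with one Maxwell element (viscosity η₁, relaxation time τ₁).
Drag couples to viscosity through Stokes' law γ = 6πηa; the model itself only
ever sees the drags, so the radius is a unit choice for reporting
viscosities.  Assumptions inherited from the model:

* overdamped motion (no inertia) — valid above microseconds for micron beads;
* a single relaxation time — generalized Maxwell fluids with several modes
  are out of scope;
* a harmonic, stationary trap and thermal equilibrium (fluctuation–
  dissipation theorem), so the embedded state (x, X) is a stationary
  Gaussian–Markov process;
* uniform sampling with negligible measurement noise; the calibration
  factor c in the observation x_n = [c, 0]·Y_n is treated as a fixed input.

Two intrinsic time scales govern everything: the fast scale
τ_S = 1/(k/γ₀ + γ₁/(γ₀τ₁)) (the sampling step should satisfy Δt ≲ τ_S) and
the memory time τ₁.  A third, often overlooked scale is the **position
correlation time (γ₀+γ₁)/k** — with the default parameter set 37 s, far
longer than τ₁ — which controls how slowly the sample variance converges.
Note that for η₁/η₀ = 100 and τ₁ = 1 s, τ_S = γ₀/(k + γ₁/τ₁) < τ₁·η₀/η₁ =
0.01 s for *any* radius; the default set gives τ_S = 0.009735 s, i.e. the
round value 0.01 s is the weak-trap approximation.

## Exact discretization and simulation

`build_ou_system` assembles λ, σ, D and the one-step quantities
F = e^(−λΔt), Σ(Δt) = σ − FσFᵀ.  The 2×2 matrix exponential uses the
closed-form spectral formula (both eigenvalues are provably real and
positive; the discriminant is bounded below by (k/γ₀ − (1+η₁/η₀)/τ₁)²); when
the eigenvalue gap satisfies ν·Δt < 10⁻⁶ it switches to scipy's
scaling-and-squaring to avoid cancellation.

The simulator draws Y₀ ~ N(0, σ) (stationary by construction — the
continuous model is prepared in the infinite past, so no burn-in) and then
applies the exact AR(1) update.  The two-state recursion is reduced to a
pair of second-order scalar difference equations and evaluated with
`scipy.signal.lfilter`; this is algebraically identical to the naive loop
(asserted to 10⁻¹² relative in the tests) and runs at C speed.  Σ(Δt) is
Cholesky-factorized with a single 10⁻¹²·tr(Σ) jitter retry before raising.
An independent Euler–Maruyama integrator with substeps cross-checks the
sampler distributionally (variance, lag correlation, two-sample KS on
thinned draws).

## Stage I: stiffness

k\* = N·k_BT/Σx²; by default no mean is subtracted (the model is zero-mean);
`center=True` exists for offset-bearing instrument data.  The textbook error
k\*/√N assumes independent samples.  Because the position decorrelates over
(γ₀+γ₁)/k, the package also reports an effective-sample-size-corrected error
using N_eff = N / Σ_l ρ_l² with ρ estimated from the data (truncated at its
first zero crossing).  At the default conditions the correction is a factor
~100: a 500 s series contains only ~10 independent samples of the variance,
so k\* genuinely scatters by ~40 % between replicates.  Any procedure that
consumes k\* downstream inherits this scatter in a strongly correlated way;
both inference routes below are self-consistent under it because the model
amplitude k_BT/k\* then matches the realized sample variance by
construction.

## Stage II: Kalman-filter likelihood and MAP fit

The filter implements the standard predict/update recursion for the
state-space pair (F, Σ, C).  With the stationary prior (Ŷ₁|₀ = 0, ω₁|₀ = σ)
the accumulated innovation likelihood is *exactly* the density of the
N-dimensional stationary Gaussian with covariance
C_ij = [e^(−λ|i−j|Δt)σ]₀₀c² — the central correctness property, asserted
against dense linear algebra at 10⁻⁸.  An alternative `init_mode='approx'`
starts from ω₁|₀ = DDᵀΔt, the small-Δt approximation of Σ(Δt); the two
likelihoods differ by a bounded amount (the filter forgets the prior over
one slow relaxation) that vanishes per observation as N grows, and the
likelihood is defined over all N observations in either case (no first
point is discarded).

The predictive covariance Riccati recursion converges geometrically; once
the change falls below 10⁻¹³·‖σ‖ the gain and innovation variance are
frozen and the remaining innovation pass — again a linear constant-
coefficient recursion in the data — is evaluated with `lfilter`.  The fast
path agrees with the plain loop to 10⁻¹⁰ and makes 10⁶-point likelihoods
take milliseconds.

MAP optimization runs over log(η₀, η₁, τ₁) (positivity plus a flat-in-log
non-informative prior) with k fixed at the stage-I estimate.  Starts are a
data-driven method-of-moments estimate from the empirical ACF (initial slope
→ γ₀; tail rate → total drag; remaining fast-rate relation → τ₁) and its
×10 / ÷10 perturbations; Nelder–Mead (fatol 10⁻⁸ nats) then a Powell
polish.  Standard errors: central finite-difference Hessian in log space
(step 10⁻⁴), checked positive definite, inverted, and mapped to natural
scale by the delta method.

## ACF route

The model ACF is evaluated by default in the matrix form [e^(−λt)σ]₀₀ via
the spectral weights w_slow = σ₀₀(μ₂−q)/ν, w_fast = σ₀₀(q−μ₁)/ν with
q = k/γ₀; the literal analytic expression in (a, b, ω₀, c, ν) is kept as a
second backend.  The two agree to 10⁻¹⁰ over all tested parameters — the
printed denominators simplify to 2s·c for s each decay rate, so the forms
are algebraically identical.

The empirical ACF uses the biased (1/N) estimator via FFT (statsmodels),
mean-centering on by default for instrument data and off for zero-mean
simulations; no binning by default (binning discards short-time
information), with the estimator verified against the direct lag sum.

Fitting maximizes the Gaussian likelihood that treats each lag's ACF
estimate as independent with common unknown variance S.  S is profiled out
analytically, leaving unweighted least squares; S is reported as the mean
squared residual.  The optimization is performed in the ordered-rate
parametrization (μ₁, q, μ₂) with μ₁ < q < μ₂ enforced through log-gap
coordinates — the raw viscosity parametrization is viciously
ill-conditioned for near-plateau ACFs (the fast mode carries only ~2.6 % of
the amplitude at the default parameters) and a simplex started far from the
optimum stalls.  Starts: the moment estimate, refined by a coarse 7³
log-grid over ±1.5 decades, then Nelder–Mead and Powell.  Errors come from
the Hessian of the profiled likelihood (N/2)·ln SSR.

The independence-across-lags assumption is knowingly false at long lags —
neighbouring ACF estimates share the same slow-mode fluctuations — and the
package deliberately implements it as stated rather than correcting the
likelihood; the fit-range sweep plus residual diagnostics surface the
consequences: estimates drift and residual variance grows once the range
extends beyond ~1 s, and the "best" range is designated by minimal summed
relative standard error.

## Synthetic data: what it does and does not emulate

The simulator *is* the study's data source (no public experimental
trajectories exist): a stationary Gaussian two-state OU process at the input
set η₀ = 1 mPa s, η₁ = 100 mPa s, τ₁ = 1 s, k = 0.1 µN/m, a = 1.95 µm,
T = 298.15 K.  It does not emulate camera localization noise, blur/finite
exposure, drift, trap anharmonicity, multiple relaxation modes, or
calibration uncertainty — so passing tests demonstrate correctness of the
inference machinery under the model, not robustness to instrument
artifacts.  Problem sizes in the tests and the acceptance script
(N ≈ 5×10⁴ replicated twenty-fold; one N ≈ 2×10⁶ series) match the study's
stated normalized conditions Ts/τ₁ ∈ {500, 2000}, Δt/τ_S ∈ {1, 0.1}.

## Attainable precision at the stated conditions

Two published precision figures deserve care.  First, the ~1 % replicate
spread quoted for the MAP parameters at Ts/τ₁ = 500, Δt/τ_S ≤ 1 holds for
η₀ only: the exact-likelihood Hessian (Cramér–Rao) bounds the relative
standard deviation of τ̂₁ at ≈ 4.6 % and η̂₁ at ≈ 4.3 % under those
conditions, and the package's replicate spread matches the bound (i.e. the
estimator is efficient; no estimator can reach 1 % there, though the
standard error of the *mean* of 20 replicates is ≈ 1 %).  Second, the
stage-I error k\*/√N is printed as defined but is ~100× optimistic for this
slowly decorrelating process; the corrected error above is the meaningful
one.  Both points are quantified by the test suite.

## Known limitations

* No measurement-noise term in the observation model (would add one
  parameter and regularize the filter at tiny Δt).
* No smoothing, missing-data handling, or non-uniform sampling.
* The joint 4-parameter fit (``fit_map(..., joint_k=True)``) exists but the
  two-stage workflow is the supported, tested path; freeing k does not
  recover the stiffness any faster because the slow mode carries little
  likelihood mass.
* Frequency-domain outputs (G*(ω)) and MSD/PSD fitting are out of scope.
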