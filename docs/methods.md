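# Methods

## Setting

A stationary bivariate diffusion (x, y) is observed every τ time units.
The object of study is the transition ζ = (x_t, y_t, x_{t+τ}, y_{t+τ})
and its time-swap ζ̃ = (x_{t+τ}, y_{t+τ}, x_t, y_t).  The stochastic
mapping irreversibility of a transition is φ = ln p(ζ) − ln p(ζ̃); its
ensemble average Φ_τ^xy = ⟨φ⟩ is a KL divergence and therefore
non-negative — a coarse-grained entropy production that depends only on
single-transition statistics and equals the irreversibility of whole
series when the underlying dynamics is Markovian.  Under stationarity the
law of the backward transition equals the law of the swapped forward one,
so all backward statistics here are block-swaps of forward covariances;
this is exact, and it is what keeps every estimated Φ a true KL ≥ 0.

In signal-response (feedback-free) dynamics, x_{t+τ} is conditionally
independent of y_t given x_t.  That missing edge yields an integral
fluctuation theorem ⟨exp(−φ + φ_x + T^st)⟩ = 1, where φ_x is the
signal-marginal irreversibility and T^st the stochastic backward transfer
entropy, and with it the bound Φ_τ^{y|x} = Φ_τ^xy − Φ_τ^x ≥ T_{y→x}(−τ).
For Gaussian ensembles every measure reduces to log-determinants of
covariance blocks:

- Φ = KL between N(0, Σ₄) and N(0, PΣ₄Pᵀ), P the block swap;
- T_{y→x}(−τ) = I(x_t; y_{t+τ} | x_{t+τ}), T_{y→x}(τ) = I(y_t; x_{t+τ} | x_t);
- C_{x→y}(τ) = I(x_t; y_{t+τ}) − R(τ) with
  R = ½ ln[e^{2(I₁+I₂)} / (e^{2I₁} + e^{2I₂} − 1)],
  I₁ = I(x_t; y_t), I₂ = I(y_{t+τ}; (x_t, y_t)).  R is evaluated in
  log-sum-exp form; its required limits (R → 0 and C → 0 as τ → ∞, C ≥ 0)
  hold throughout the tested parameter range, so the adopted reading of
  the redundancy formula is retained.

All logarithms are natural; every reported quantity is in nats (the CLI
offers a bits conversion at the output layer only).  Log-determinants are
always computed from Cholesky factors, which keeps them stable to
condition numbers around 1e12; matrices that fail Cholesky raise a named
error, and regularization (jitter) happens only when explicitly requested.
Results in (−1e-10, 0) are clipped to zero and logged as cancellation
noise; anything more negative raises, since it indicates inconsistent
inputs rather than round-off.

## The linear engine

For the linear model dx = −x/t_rel dt + D dW, dy/dt = αx − βy the
stationary covariance solves AΣ + ΣAᵀ + diag(D², 0) = 0 with the
triangular drift A = [[−1/t_rel, 0], [α, −β]]; the closed form
Σxx = D²t_rel/2, Σxy = αΣxx/(β + 1/t_rel), Σyy = αΣxy/β is used directly
(the scipy Lyapunov solver serves as an independent oracle in the tests).
The lagged joint covariance has blocks Σ on the diagonal and e^{Aτ}Σ in
the cross positions.  Everything else — Φ, Φ_x (identically zero: the OU
autocovariance is symmetric in its two times), both transfer entropies,
causal influence, the ψ density — is derived from this 4×4 matrix.
Closed-form special cases worth knowing:

- the response noise is taken exactly zero, so y is a noiseless linear
  functional of the x history; consequently every information measure is
  independent of α and of D (scale-free), and depends only on βt_rel and
  τ/t_rel;
- the steady-state information flow collapses to αΣxy/Σyy = β: the
  response bandwidth *is* the flow, at any coupling scale.  It is exposed
  as the covariance expression and cross-checked in the tests against a
  2-D quadrature of the defining integral and against the finite-difference
  slope of the causal influence at small τ.  Note the α → 0 limit is
  singular: with any nonzero coupling the flow is β, at exactly zero
  coupling it is 0 — an artifact of the noiseless-response idealization.

Correlations decay like exp(−τ·min(1/t_rel, β)), and the measures like
their square; beyond roughly 35 relaxation times the float64 path returns
cancellation noise.  The `dps` option re-evaluates the same expressions in
arbitrary precision (mpmath) from the closed-form blocks; `suggested_dps`
sizes the precision from the decay exponent plus a 40-digit margin.  The
large-lag limit ratios Φ/T_bwd → 2 and Φ/C → 8 are recovered at machine
accuracy this way for any βt_rel.

The ψ density at a state (x_t, y_t) is the stationary density times the
KL divergence between the forward conditional p(z_{t+τ}|z_t) and the
backward conditional p(z_{t−τ}|z_t), both Gaussian with state-linear
means, so ψ = p(z)·(c₀ + ½ zᵀMz) with constant c₀ ≥ 0 and M ⪰ 0.  Grids
default to ±6 SD with 400 points per axis (trapezoid quadrature recovers
Φ to well under 1%); axes are expressed in stationary-SD units and carry
the Jacobian, so the quadrature over the plotted grid is Φ itself.
Spanning less than ±4 SD logs a warning.

## Simulation

Both models are integrated by Euler–Maruyama (the models are Ito SDEs; no
higher-order scheme is warranted, and a dt-halving test bounds the bias).
Default steps: dt = min(t_rel, 1/β)/100 for the linear model and
dt = 1e-3 for the receptor-ligand model; a step above 1% of the fastest
timescale raises unless explicitly overridden.  Burn-in defaults to ten
times the slowest relaxation time.  The receptor-ligand constraint
0 < y < 1 is enforced by hard clamping at ε = 1e-9 with a clamp-rate
monitor (warning above 0.1% of steps); reflection was rejected because it
perturbs the stationary law more than clamping at this ε.  Replicated
short runs, vectorized across replicas with one seeded generator, supply
decorrelated transition samples; a single long run is the one-replica
special case.  Identical configurations reproduce series bit for bit.

## Estimation

Estimators fit one zero-mean (after centering) Gaussian to the n×4
transition sample and evaluate the same covariance functionals as the
analytic engine — the conditionals of a joint Gaussian are Gaussian, so
this is the joint-Gaussian approximation of the transition probabilities,
and the lowest-variance version of it.  Backward statistics are the
block-swap of the fitted forward covariance, never a separate fit to
reversed series (halving the variance and guaranteeing Φ̂ ≥ 0).  The
plug-in Φ̂ has a positive O(d²/n) bias on reversible inputs; it is
documented, tested, and deliberately not corrected by default.  An
optional Ledoit–Wolf shrinkage flag exists for short series and is off
everywhere else.  Ensembles below 100 samples are rejected, below 10⁴ a
warning is logged.  Overlapping windows are used when slicing series into
transitions; error bars that must respect the resulting serial dependence
use a moving-block bootstrap (block length configurable).

The mapping irreversibility is invariant under marginal coordinate
changes applied identically at both times, but the Gaussian approximation
is not.  For the receptor-ligand model the estimators therefore work in
log(x), logit(y) coordinates, where the multiplicative noises x dW and
y(1−y) dW become near-additive and the fitted Gaussian is faithful; in
raw coordinates the same fit underestimates the short-lag irreversibility
severalfold.  `transform_series` makes this an explicit, domain-checked
step; the estimator itself always consumes the ensemble as given.

The binned ψ estimate takes the conditional laws from the global Gaussian
fit, evaluates the per-sample KL, and averages it within occupancy bins;
the occupied-bin quadrature then approaches the fitted-Gaussian Φ̂ as bins
refine, with finite-n deficits from masked fringe bins (default mask:
fewer than 200 samples) and grid truncation at ±5 SD — a few percent at
n ≈ 10⁶.

## Fluctuation-theorem checks

`ift_check` evaluates the per-sample exponent under an analytic reference
law and averages its exponential.  The plain average is unbiased but
heavy-tailed: exp(−φ) has finite variance only when 2Σ̃⁻¹ − Σ⁻¹ ≻ 0, and
at the reference conditions used for the standard theorem (τ=5, β=0.2,
t_rel=10, Φ ≈ 3.9 nats) that condition fails, so the plain sample mean
systematically undershoots 1 at any feasible n — the same pathology as
Jarzynski averaging of large dissipated work.  The `bridge` method
estimates the identical integral ∫ p(ζ̃) dζ = 1 from two independent
half-ensembles, one kept as forward draws and one block-swapped into
backward draws, with mixture importance weights p̃/((p + p̃)/2) bounded by
2 — the two-distribution construction behind Bennett's acceptance-ratio
method.  It is the default choice whenever Φ exceeds a nat or two.  Using
the *same* samples for both halves makes the paired weights identically
2 and the check vacuous; the implementation therefore splits the ensemble.
The signal-response exponent −φ + φ_x + T^st is far better behaved (its
mean is Φ − Φ_x − T_bwd, the slack in the bound) and is checked with the
plain average.

## Problem sizes and reproducibility

The acceptance script simulates the receptor-ligand model at dt = 1e-3
with 100 replicas × 10⁵ post-burn-in steps (10⁷ total), sampled every
0.05, and draws 10⁶ exact transition samples for the fluctuation
theorems; the unit-test suite runs the same pipelines at roughly a tenth
of those sizes.  All randomness descends from a single seed through named
sub-streams, so every figure-level number in the examples and the
acceptance output is reproducible bit for bit.

## What the generators do and do not emulate

The bundled models produce stationary, Markovian, uniformly sampled,
noise-free-measurement series.  Passing tests therefore demonstrate
correctness of the measures and estimators under those conditions; they
do not address measurement noise, non-stationarity (trends, relaxation
ensembles), irregular sampling, or non-Markovian latent dynamics, all of
which bias irreversibility estimates in real recordings.  The Gaussian
estimators are consistent for the *Gaussian* functionals of the chosen
coordinates; strongly non-Gaussian dynamics without a good Gaussianizing
coordinate change will be underestimated.  Known further limitations:
bivariate only; single-lag transition statistics (non-Markovian whole-series
irreversibility is out of scope); no nonparametric (k-NN/kernel)
information estimators.
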