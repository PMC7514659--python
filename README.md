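# infotherm

Information thermodynamics for bivariate time series of signal-response
systems: how irreversible is a sampled trajectory of a signal `x` driving a
response `y`, and how much of that irreversibility is information flow?

`infotherm` is a library (with a thin `infotherm` CLI) for researchers in
stochastic thermodynamics and systems biology who work with stationary
bivariate series sampled at a finite observational time τ — simulated
signal–response dynamics, receptor occupancy traces, or any pair of coupled
stochastic observables.

## The measures

For a stationary series sampled every τ, form the transition
ζ = (x_t, y_t, x_{t+τ}, y_{t+τ}) and its time-swap
ζ̃ = (x_{t+τ}, y_{t+τ}, x_t, y_t).  The package computes, in nats:

- **Mapping irreversibility**  Φ_τ^xy = ⟨ln p(ζ)/p(ζ̃)⟩ — the KL divergence
  between the forward transition law and its time reversal; a coarse-grained
  entropy production for time series.
- **Marginal and conditional irreversibility**  Φ_τ^x (signal alone) and
  Φ_τ^{y|x} = Φ_τ^xy − Φ_τ^x.
- **Backward transfer entropy**  T_{y→x}(−τ) = I(x_t ; y_{t+τ} | x_{t+τ}),
  the transfer entropy of time-reversed trajectories.  In feedback-free
  (signal-response) dynamics it obeys the second-law-like bound
  Φ_τ^{y|x} ≥ T_{y→x}(−τ), with the matching integral fluctuation theorem
  ⟨exp(−φ_τ^xy + φ_τ^x + T^st_{y→x}(−τ))⟩ = 1.
- **Causal influence**  C_{x→y}(τ) = I(x_t ; y_{t+τ}) − R(τ), the lagged
  mutual information net of the redundancy R(τ) already carried by y_t.
- **Horowitz–Esposito information flow**  I_{x→y}, the steady-state rate the
  causal influence converges to as τ → 0.
- **Irreversibility density**  ψ(x_t, y_t), the decomposition of Φ_τ^xy over
  current states.

Two engines are provided.  For the **basic linear response model**
(OU signal, noiseless linear response)

    dx = −x/t_rel dt + D dW,      dy/dt = αx − βy

everything is exact, via the stationary Lyapunov solution and the matrix
exponential of the drift (an arbitrary-precision path covers extreme lags,
where correlations fall below float64 resolution).  For nonlinear models —
the bundled **receptor-ligand system**

    dx = −(x−1) dt + x dW_x
    dy = [k_on (1−y) x^h/(1+x^h) − k_off y] dt + y(1−y) dW_y

— a seeded Euler–Maruyama simulator and joint-Gaussian estimators (with
marginal Gaussianizing transforms, log for the ligand and logit for the
occupancy) recover the same measures from data.

## Worked example

```python
from infotherm import BLRMParams, irreversibility

params = BLRMParams(trel=10.0, D=1.0, alpha=1.0, beta=0.2)
for tau in (5.0, 20.0, 50.0):
    r = irreversibility(params, tau)
    print(f"tau={tau:5.1f}  phi_xy={r.phi_xy:.4f}  bte={r.bte:.4f}  "
          f"phi/bte={r.phi_xy/r.bte:.3f}  phi/C={r.phi_xy/r.causal_influence:.3f}")
```

prints

```
tau=  5.0  phi_xy=3.8925  bte=0.6379  phi/bte=6.102  phi/C=10.736
tau= 20.0  phi_xy=0.1253  bte=0.0592  phi/bte=2.119  phi/C=7.659
tau= 50.0  phi_xy=0.0004  bte=0.0002  phi/bte=2.000  phi/C=7.965
```

All measures decay with the observational time, and the ratios approach
their universal limits: the mapping irreversibility is asymptotically
**twice** its backward-transfer-entropy lower bound and **eight** times the
causal influence, for any parameter choice of the linear model.  The
`examples/` directory has one narrative script per capability (analytic
measures, fluctuation theorems, receptor-ligand τ-scan, irreversibility
density); each prints its numbers with a line on what they mean.  The same
operations are available from the shell, e.g.

```sh
infotherm blrm --trel 10 --beta 0.2 --tau 50 --out report.json
infotherm simulate --model rl --dt 1e-3 --steps 200000 --burn-in 10 \
    --store-every 0.05 --seed 1 --out series.tsv
infotherm estimate --series series.tsv --tau 0.5 \
    --x-transform log --y-transform logit
```

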