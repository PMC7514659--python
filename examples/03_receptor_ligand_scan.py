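"""Irreversibility of a simulated receptor-ligand system across lags.

Simulates ligand fluctuations (mean-reverting geometric Brownian motion,
mean 1) driving receptor activation through Hill kinetics (kon=5,
koff=1, h=2), then estimates the mapping irreversibility and backward
transfer entropy at each observational time tau with the joint-Gaussian
approximation in log/logit coordinates.  The run is scaled to ~2x10^6
Euler steps so the script finishes in seconds; the acceptance script
uses 10^7.
"""

import numpy as np

from infotherm import RLParams, SimConfig, simulate_receptor_ligand, tau_scan

cfg = SimConfig(
    dt=1e-3, n_steps=100_000, burn_in=10.0, seed=3, n_replicas=20,
    store_every=0.05,
)
series = simulate_receptor_ligand(RLParams(kon=5.0, koff=1.0, h=2.0), cfg)
grid = np.concatenate([[0.05], np.round(np.arange(1, 31) * 0.1, 10)])
scan = tau_scan(series, grid, x_transform="log", y_transform="logit")

tbl = scan.table
print(f"{'tau':>5} {'phi_xy':>9} {'bte':>9}")
show = np.isclose(tbl["tau"].to_numpy()[:, None],
                  [0.05, 0.1, 0.3, 0.5, 1.0, 2.0, 3.0]).any(axis=1)
for _, row in tbl[show].iterrows():
    print(f"{row['tau']:5.2f} {row['phi_xy']:9.4f} {row['bte']:9.4f}")

print()
print(f"Optimal observational time (argmax phi_xy): {scan.argmax_tau:.2f}")
print(f"Small-tau irreversibility rate phi_xy/tau -> {scan.small_tau_rate:.2f} nats/time")
print()
print("The irreversibility peaks at an interior tau (~0.3-0.5): sampling much")
print("faster than the kinetics sees mostly noise, sampling much slower loses")
print("the memory of the coupling; the backward transfer entropy is roughly")
print("half of phi_xy and is the cheaper lower bound (3-D vs 4-D statistics).")
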