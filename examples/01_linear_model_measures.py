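"""Exact irreversibility measures of the linear signal-response model.

Builds the analytic lagged Gaussian for an OU signal (trel=10) driving a
deterministic linear response (beta=0.2) and prints the mapping
irreversibility, backward transfer entropy and causal influence across
observational times, ending with the large-lag ratios: the
irreversibility is asymptotically twice its backward-transfer-entropy
lower bound and eight times the causal influence.
"""

from infotherm import BLRMParams, information_flow, irreversibility

params = BLRMParams(trel=10.0, D=1.0, alpha=1.0, beta=0.2)

print(f"{'tau':>6} {'phi_xy':>10} {'bte':>10} {'causal':>10} {'phi/bte':>8} {'phi/C':>8}")
for tau in (0.5, 2.0, 5.0, 10.0, 20.0, 50.0):
    r = irreversibility(params, tau)
    print(
        f"{tau:6.1f} {r.phi_xy:10.4f} {r.bte:10.4f} {r.causal_influence:10.4f} "
        f"{r.phi_xy / r.bte:8.3f} {r.phi_xy / r.causal_influence:8.3f}"
    )

print()
print("All quantities in nats.  phi_xy diverges as tau -> 0 (the response is")
print("noiseless, so short-lag transitions are sharply oriented in time) and")
print("every measure decays to zero as tau -> infinity; the ratios approach")
print("their universal limits 2 and 8.")
print(f"Steady-state information flow: {information_flow(params):.4f} nats/time "
      f"(= beta exactly; the response bandwidth sets the flow).")
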