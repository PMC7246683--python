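"""Single-channel SIS purchase dynamics and the R0 = beta*N/gamma threshold.

Simulates one sales channel on either side of the threshold and prints the
terminal purchaser count against the endemic prediction N*(1 - 1/R0).
"""

from dualsis import SingleChannelParameters, simulate_single

for beta in (0.00005, 0.0005):
    params = SingleChannelParameters(beta=beta, gamma=0.1, N=1000.0)
    R0 = params.reproduction_number
    traj = simulate_single(params, I0=1.0, t_end=500.0)
    S, I = traj.terminal_state
    endemic = params.N * (1 - 1 / R0) if R0 > 1 else 0.0
    print(f"R0 = {R0:4.1f}: purchasers at t=500 -> {I:8.3f} "
          f"(endemic prediction {endemic:8.3f}), S+I = {S + I:.6f}")

print("\nBelow R0 = 1 purchasing dies out; above, it settles at N*(1 - 1/R0).")
print("S + I stays pinned at N: the customer population is closed.")
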