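"""Equilibria and thresholds of the dual-channel model.

Uses the bistable study parameter set (strong channel competition,
sub-threshold offline transmission) and prints the demand equilibria, the
reproduction numbers, and the full four-dimensional equilibrium table.
"""

from dualsis import (ModelParameters, demand_equilibria_2d,
                     enumerate_equilibria_4d, equilibria_to_frame,
                     interior_thresholds, reproduction_numbers)

params = ModelParameters(r1=1.0, r2=1.0, K1=1000.0, K2=1000.0, m=-1.2, n=-1.5,
                         beta11=0.000005, beta12=0.05, beta21=0.05,
                         beta22=0.05, gamma1=0.01, gamma2=0.01)

R1, R2 = reproduction_numbers(params)
ts = interior_thresholds(params)
print(f"regime: {ts.regime}   R1 = {R1}   R2 = {R2}")
print(f"A = {ts.A:.6f} (= gamma1), B = {ts.B:.6f} (= gamma2)\n")

print("Demand equilibria (N1, N2):")
print(equilibria_to_frame(demand_equilibria_2d(params)).to_string(index=False))
print("\nFull equilibria (N1, I1, N2, I2):")
print(equilibria_to_frame(enumerate_equilibria_4d(params)).to_string(index=False))
print("\nR1 = 0.5 < 1, so the offline endemic point P2 is absent: offline")
print("purchasing cannot sustain itself at this transmission rate.")
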