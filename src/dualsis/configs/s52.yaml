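# Scenario s52 — online transmission sweep in the channel-2-dominant regime.
#
# Calibration note: demand growth rates r1 = r2 = 1, purchase-termination
# rates gamma1 = gamma2 = 0.01 (same calibration as s51).
r1: 1.0
r2: 1.0
K1: 1000.0
K2: 1000.0
m: -1.2
n: -0.5
beta11: 0.00005
beta12: 0.00005
beta21: 0.00005
beta22: 0.000005   # overridden by the sweep below
gamma1: 0.01
gamma2: 0.01
N1_0: 100.0
I1_0: 1.0
N2_0: 100.0
I2_0: 1.0
t_end: 10.0
sweep:
  beta22: [0.000005, 0.00003, 0.00006, 0.00009]
notes: >
  Channel-2-dominant regime (r1*r2 > m*n, r1 < -m, r2 > -n): online demand
  wins in the long run and the sweep crosses the online threshold R2 = 1.
  The short horizon t = 10 probes the transient ordering, not convergence.
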