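# Scenario s51 — offline transmission sweep in the bistable demand regime.
#
# Calibration note: the demand growth rates are r1 = r2 = 1 and the
# purchase-termination rates gamma1 = gamma2 = 0.01; the first sweep value
# is pinned by the sub-threshold check R1 = beta11*K1/gamma1 = 0.5 < 1
# (which requires gamma1 = 0.01, not 1).
# Initial purchased customers default to one seed per channel: an SIS
# system started at I = 0 stays at I = 0 forever.
r1: 1.0
r2: 1.0
K1: 1000.0
K2: 1000.0
m: -1.2
n: -1.5
beta11: 0.000005   # overridden by the sweep below
beta12: 0.05
beta21: 0.05
beta22: 0.05
gamma1: 0.01
gamma2: 0.01
N1_0: 100.0
I1_0: 1.0
N2_0: 100.0
I2_0: 1.0
t_end: 300.0
sweep:
  beta11: [0.000005, 0.00003, 0.00006, 0.00009]
notes: >
  Bistable regime (r1*r2 < m*n, r1 < -m, r2 < -n): the demand trajectory
  from (100, 100) settles on the offline-dominant attractor, and the sweep
  crosses the single-channel threshold R1 = 1 between the first and second
  values.
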