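# Scenario s53 — joint cross-transmission sweep in the coexistence regime.
#
# Calibration note: demand growth rates r1 = r2 = 1, purchase-termination
# rates gamma1 = gamma2 = 0.01.  The within-channel rates are held fixed
# (beta11 = 0.00002, beta22 = 0.00001) and the two cross-channel rates are
# swept jointly over parallel value lists; the sweep crosses the invasion
# threshold Pi1 = Pi2 between the first and second pairs.
r1: 1.0
r2: 1.0
K1: 1000.0
K2: 1000.0
m: -0.8
n: -0.5
beta11: 0.00002
beta12: 0.000005   # overridden by the sweep below
beta21: 0.000003   # overridden by the sweep below
beta22: 0.00001
gamma1: 0.01
gamma2: 0.01
N1_0: 100.0
I1_0: 1.0
N2_0: 100.0
I2_0: 1.0
t_end: 10.0
sweep:
  beta12: [0.000005, 0.00001, 0.00002, 0.00005]
  beta21: [0.000003, 0.00001, 0.00002, 0.00005]
notes: >
  Coexistence regime (r1*r2 > m*n, r1 > -m, r2 > -n): demand settles at the
  interior equilibrium M = (N1E, N2E); purchases persist in both channels
  only past the invasion threshold Pi1 < Pi2, where the interior endemic
  point P6 exists.
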