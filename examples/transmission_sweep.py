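"""Offline transmission sweep: total sales across the R1 = 1 threshold.

Runs the shipped bistable sweep (beta11 over four values) and prints the
summary: below R1 = 1 offline purchasing fades out; above it, terminal
offline sales approach the endemic level K1*(1 - 1/R1), and total sales
increase monotonically with the transmission rate.
"""

from dualsis import builtin_scenario, monotonicity_check, run_sweep

result = run_sweep(builtin_scenario("s51"))
cols = ["beta11", "R1", "terminal_I1", "terminal_total_sales",
        "matched_equilibrium"]
print(result.summary[cols].to_string(index=False))

verdict = monotonicity_check(result.summary)
print(f"\nterminal total sales nondecreasing in beta11: {verdict.nondecreasing}")
print("Endemic predictions K1*(1-1/R1) for R1 = 3, 6, 9: "
      f"{1000*(1-1/3):.1f}, {1000*(1-1/6):.1f}, {1000*(1-1/9):.1f}")
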