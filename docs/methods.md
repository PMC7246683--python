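# Methods

## Model

The package implements a two-channel market as a coupled
demand–transmission system.  Demand: the channel totals (N₁, N₂) follow
Lotka–Volterra competitive logistic growth,

    N₁' = N₁·g₁,   g₁(N₁, N₂) = r₁(1 − N₁/K₁) + m·N₂/K₂
    N₂' = N₂·g₂,   g₂(N₁, N₂) = r₂(1 − N₂/K₂) + n·N₁/K₁,

with carrying capacities Kᵢ (persons), intrinsic growth rates rᵢ (per unit
time) and signed cross-influence rates m, n (competition ⇔ both negative).
Transmission: within each total, purchased customers Iᵢ follow SIS
dynamics with mass-action incidence within and across channels,

    Iᵢ' = (βᵢᵢIᵢ + βᵢⱼIⱼ)(Nᵢ − Iᵢ) − γᵢIᵢ + gᵢ·Iᵢ,

where βᵢⱼ is the rate at which purchasers of channel j convert potential
customers of channel i, and γᵢ is the purchase-termination rate.  The
demographic term gᵢIᵢ scales the purchased subpopulation with its
channel's growth; it makes Iᵢ ≤ Nᵢ forward-invariant (at I₁ = N₁,
(I₁ − N₁)' = −γ₁N₁ ≤ 0) and vanishes identically at every equilibrium the
analysis studies, because gᵢ = 0 on the interior demand nullclines and at
the corner equilibria.  Since reasonable variants of the model differ
exactly in this term, it is a switch (`demographic_coupling`, default on);
every closed form, threshold and stability verdict in the package holds
under either setting, and the test suite checks the equilibrium
stationarity both ways.

Assumptions inherited from the model class: identical products in both
channels; one channel per purchase; a closed consumer population per
channel apart from logistic demand growth; no immunity after purchase
termination (SIS, not SIR); deterministic mean-field dynamics.

## Analysis

**Equilibria.**  The demand system has corner equilibria O(0,0), P(K₁,0),
Q(0,K₂) and the interior point M = ((m+r₁)r₂K₁/(r₁r₂−mn),
(n+r₂)r₁K₂/(r₁r₂−mn)), which lies in G exactly in the coexistence regime
(r₁r₂ > mn, r₁ > −m, r₂ > −n) or the bistable regime (all three reversed),
both requiring m, n < 0.  A vanishing denominator r₁r₂ − mn is reported as
a nonexistence flag, not an exception.  The full system adds P₀, P₁, P₃
(always), the boundary endemic points P₂ = (K₁, K₁(1−1/R₁), 0, 0) and
P₄ = (0, 0, K₂, K₂(1−1/R₂)) above the reproduction-number thresholds
Rᵢ = βᵢᵢKᵢ/γᵢ > 1, the demand-interior point P₅, and the interior endemic
point P₆.

**P₆ root-finding.**  At M the balance equations reduce to
(β₁₁I₁ + β₁₂I₂)(N₁E − I₁) = γ₁I₁ and its mirror.  For fixed I₂ the first
equation is a concave quadratic in I₁ whose relevant (largest) root is
taken in closed form, using the cancellation-free branch of the quadratic
formula (2c/(√(b²+4ac) − b) when b < 0) — the naive branch loses all
significant digits near the invasion threshold and can fabricate a
spurious root at the origin.  The residual of the second equation along
I₁*(I₂) is then bracketed on (0, N₂E) and solved by Brent iteration
(xtol 10⁻¹³ of scale), falling back to a 512-point sign-change scan when
the endpoint signs do not bracket.  No sign change ⇒ P₆ nonexistent,
consistent with the invasion criterion below.  When β₁₂ = β₂₁ = 0 the
channels decouple and the two single-channel closed forms are used.

**Thresholds.**  A = γ₁ − r₁(1 − N₁E/K₁) − m·N₂E/K₂ and B symmetric are
computed from their defining expressions; A = γ₁ and B = γ₂ identically at
M (the growth terms vanish), which the tests assert to 10⁻⁹ as a built-in
self-check.  Purchasing invades P₅ iff Π₁ = (A − β₁₁N₁E)/(β₁₂N₁E) <
Π₂ = β₂₁N₂E/(B − β₂₂N₂E), on the domain A − β₁₁N₁E > 0, B − β₂₂N₂E > 0.
This is equivalent to the next-generation matrix
[[β₁₁N₁E/γ₁, β₁₂N₁E/γ₁], [β₂₁N₂E/γ₂, β₂₂N₂E/γ₂]] having spectral radius
above 1; the equivalence is verified on sampled parameter sets rather than
assumed.

**Stability.**  The Jacobian is analytic and block lower-triangular in the
ordering ((N₁, N₂), (I₁, I₂)) — purchasers never feed back on demand — so
its spectrum is the union of the demand block and the infection block.
Verdicts use the eigenvalue real parts with a nonhyperbolicity tolerance
of 10⁻⁸·max(r₁, r₂, γ₁, γ₂); anything within tolerance of the imaginary
axis is reported "nonhyperbolic", never silently classified.  The
threshold condition table maps each regime and inequality set to a claimed
attractor and its attraction region Ω₁…Ω₁₃.  Claims on open regions are
cross-validated two ways: eigenvalues, and trajectory convergence from a
sampled state inside the region (basin membership decided by forward
simulation of the demand system — the defining property of a basin).
Claims restricted to the separatrix (Ω₁₂, Ω₁₃), a measure-zero set, are
validated structurally: the point must be a saddle with exactly one
unstable direction, the one transverse to the stable manifold on which
attraction is claimed.  In the coexistence regime M is an attracting node
of the demand system (and P₅/P₆ can attract in the full system), while in
the bistable regime M is a saddle; the package reports computed
eigenvalues in all cases rather than imposing a blanket saddle claim.

**Phase plane.**  Nullclines are straight lines returned as polylines.
The separatrix is traced by integrating the demand flow backward in time
from M ± ε·v_stable (ε = 10⁻⁴·max K) until the boundary of a slightly
enlarged G or a horizon of 80/min(r₁, r₂); the origin branch is snapped
onto O.  Basin membership of a query point uses a shapely polygon closed
through the lower-right boundary of G; points within 10⁻⁶·max K of the
curve are "on-curve".  "≠ 0" in the Ω-region definitions is tested as
> 10⁻⁹·max K.

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
  rtol 10⁻⁹, atol 10⁻¹², dense output on a 1000-point grid by default.
  States that leave G′ by more than 10⁻⁶ relative are flagged on the
  trajectory; smaller excursions are clipped.
* Convergence detection: an equilibrium is "reached" when every state in
  the final 10% of the horizon lies within 10⁻³ relative of its
  coordinates; among multiple matches the closest wins.
* Cross-validation horizons adapt to the target: 30/(slowest contraction
  rate of the target's Jacobian), escalating ×5 when undecided.
* Region membership and equilibrium verification: 10⁻⁹ relative /
  10⁻¹² absolute.  Regime classification treats inequalities within
  10⁻¹² of a boundary as degenerate rather than assigning a label;
  condition-table evaluation uses 10⁻⁹ relative for R = 1, Π₁ = Π₂ and
  margin boundaries.
* Equilibrium distinctness (for counting): pairwise distance above
  10⁻⁶·max(K₁, K₂).

## Parameter sampler

`sample_parameters(regime, n, seed)` rejection-samples
r ~ U(0.5, 2), K ~ U(500, 2000), m, n ~ U(−2, −0.05),
β ~ log-U(10⁻⁶, 10⁻¹), γ ~ U(0.005, 0.1), keeping sets whose regime
inequalities hold with margin ≥ 10⁻³.  The ranges put the reproduction
numbers and invasion thresholds on both sides of their critical values so
that every condition row of the stability table is exercised; draws are
deterministic for a fixed seed.

## Scenarios

The three shipped sweeps use K₁ = K₂ = 1000, r₁ = r₂ = 1,
γ₁ = γ₂ = 0.01, N₁(0) = N₂(0) = 100, I₁(0) = I₂(0) = 1:

* **s51** (bistable, m = −1.2, n = −1.5, β₁₂ = β₂₁ = β₂₂ = 0.05,
  t = 300): β₁₁ ∈ {5·10⁻⁶, 3·10⁻⁵, 6·10⁻⁵, 9·10⁻⁵}, crossing R₁ = 1.
* **s52** (channel-2-dominant, m = −1.2, n = −0.5,
  β₁₁ = β₁₂ = β₂₁ = 5·10⁻⁵, t = 10): β₂₂ over the same four values,
  crossing R₂ = 1.
* **s53** (coexistence, m = −0.8, n = −0.5, β₁₁ = 2·10⁻⁵, β₂₂ = 10⁻⁵,
  t = 10): (β₁₂, β₂₁) swept jointly over parallel lists crossing the
  invasion threshold Π₁ = Π₂.

The initial purchased counts are a design choice: one seed purchaser per
channel, because an SIS system started at I = 0 remains there, so some
seed is logically required for sales to develop; sweep conclusions are
asserted as orderings and threshold comparisons, not as point-for-point
curve values, since they depend mildly on the seed size.  At the s51
horizon t = 300 the sub-threshold run (R₁ = 0.5) is still in its slow
terminal decay (rate γ₁(1 − R₁) = 0.005 per unit time, so offline sales
are ≈ 138 of K₁ = 1000 at t = 300); the asymptotic statement — offline
sales vanish — is checked on an extended horizon, while supra-threshold
runs are within 1% of their endemic levels already at t = 300.  The s52
and s53 horizons (t = 10) probe transient ordering only, and the tests
treat them that way.

## What the synthetic conditions do and do not show

All inputs are synthetic: printed study parameter sets plus the seeded
sampler.  Passing tests demonstrate internal mathematical consistency —
closed forms solve the stated equations, thresholds match their spectral
characterizations, the condition table matches eigenvalues and simulated
attraction, conservation holds — under parameter ranges a practitioner
would consider plausible for slow retail dynamics.  They do not
demonstrate that any real pharmaceutical market follows these dynamics:
the model has identical products, homogeneous mixing, constant rates, no
pricing, and mean-field determinism.  Calibration to sales data is out of
scope.

## Known limitations

* Basins are computed in the 2D demand projection only (the demand
  subsystem is autonomous, so this is exact for the N-coordinates, but no
  4D invariant-manifold computation is attempted).
* No symbolic closed form for P₆; the deterministic bracketed solve is
  used everywhere.
* Nonhyperbolic and boundary-threshold cases are flagged, not resolved
  (no center-manifold analysis).
* More than two channels, stochastic variants, and demographic
  birth/death beyond the logistic term are out of scope.
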