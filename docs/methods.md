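# Methods

## Model

A non-porous magnesium pellet (slab, rod or ball; geometry index d = 0, 1, 2)
corrodes in an aqueous environment with inexhaustible ambient water and
CO2/bicarbonate.  Two surface reactions, Mg + 2H2O → Mg(OH)2 + H2 at r = α(t)
and Mg(OH)2 + CO2 → MgCO3 + H2O at r = β(t), deposit two porous product
layers whose outer surface r = S(t) moves with the local solid velocity.
Hydrogen leaves the system; the intermediate magnesium bicarbonate is treated
as short-lived and ignored; pH and temperature are constant (buffered
medium).  All reactions occur at the interfaces only; the pellet corrodes
smoothly (no pitting or cracking) so one spatial coordinate suffices.

Each layer is a homogeneous porous medium with solid volume fraction εᵢ.
Incompressibility plus conservation of solid and fluid volume give algebraic
radial velocity fields, every term of the form const/r^d.  Dissolved water
(mass concentration W) and CO2 (C) obey advection–diffusion equations in the
pore space; the advective velocity is the pore-fluid velocity v_f in the
default model (two alternatives are provided, see "Advection modes").

Total magnesium conservation fixes the outer radius algebraically from the
interface positions (see README).  The simulator therefore never integrates
S as an ODE: it is recomputed from α, β at every evaluation, which enforces
the global mole balance to round-off and provides a free runtime invariant
(`magnesium_balance_residual`, checked after every phase).

### Phases and interface conditions

Two reaction regimes are distinguished by the dimensionless Mg–water rate κ:

* **Case 1 (κ = ∞, instantaneous)**: water is fully exhausted at the Mg
  surface, W(α) = 0, and the interface follows the Stefan condition
  −(1−ε1)·D_W·∂rW|α = 2γ0·α̇ (two waters per Mg).  Phases: P1_1 (core
  shrinking) → P1_2 (α = 0, hydroxide shrinking) → done.
* **Case 2 (κ < ∞)**: the surface reaction follows the law of mass action,
  γ0·α̇ = −κ·W(α)², combined with the same flux balance.  Early on the
  carbonate shell is so thin that CO2 reaches the reaction site unconsumed
  and hydroxide converts on production: α = β (phase P2_1) with
  γ0·β̇ = −κ·W(β)² and Robin fluxes delivering one net H2O and one CO2 per
  converted Mg.  Once CO2 is first exhausted at the interface (t = T_ab) the
  hydroxide layer grows (P2_2), and after Mg exhaustion (Tα) phase P2_3
  mirrors P1_2.

At β (when distinct from α): C(β) = 0 (CO2 consumed on contact), water is
continuous, and the jump in water flux plus the CO2 flux set β̇ relative to
the local solid velocity:  β̇ − v_s1(β) = −(1−ε2)·∂rC|β / γ2.  Because
γ2 ≈ 1605 (ambient CO2 is three orders of magnitude more dilute than water),
this conversion is slow: it is the rate-limiting step of the whole process
and the reason Tβ ≫ Tα.

A consequence worth stating explicitly: **β is not monotone**.  While the Mg
core converts, the solid velocity v_s1(β) = −(ωα−1)·α̇·(α/β)^d > 0 dominates
the slow carbonation term, so the hydroxide–carbonate interface moves
*outward* (peaking near ωα^(1/(d+1))·S0); it recedes monotonically only
after Tα.  α is always non-increasing and S always non-decreasing (both
follow from the conservation identity with ωα, ωβ > 1), and those are the
monotonicity invariants the tests assert.

## Parameters

Dimensional inputs (`PhysicalParameters`) are in cm / g / day: diffusivities
D_W = 2.85 and D_C = 1.66 cm²/day, molar masses and layer densities of Mg,
Mg(OH)2 and MgCO3, ambient concentrations W0* = 1 and C0* = 0.0011 g/cm³,
and the three free parameters of the model — the surface rate k (cm⁴/(g·day))
and the solid fractions ε1, ε2.  Lengths scale with the reference S0* (1 cm
by default) and time with the CO2 diffusion timescale S0*²/D_C (≈ 14.5 h per
dimensionless unit).

The dimensionless groups are DW = D_W/D_C, γ0 = M_W·ρ0/(M0·W0*) = 1.2889,
γ1 = M_W·ρ1/(M1·W0*) = 0.7225, γ2 = M_C·ρ1/(M1·C0*) = 1605.5, and
κ = S0*·W0*·k/D_C.  Infinite k is carried as an explicit infinity flag —
Case 1 selects different boundary conditions rather than approximating a
stiff limit with a large float.

Two tabulation quirks are handled deliberately:

* The tabulated DW is 1.5625 while the diffusivity ratio gives
  2.85/1.66 ≈ 1.7169.  `nondimensionalize` computes the ratio from its
  inputs; the benchmark presets carry the tabulated 1.5625 (the value the
  reference simulations evidently used).  The discrepancy moves desk-scale
  timescales by only a few percent.
* The benchmark base case is quoted as "κ ≈ 0.04", corresponding to
  k = 0.07 cm⁴/(g·day); the presets use the underlying κ = 0.07/1.66 ≈
  0.0422 rather than the rounded 0.04.  The distinction is visible in the
  early CO2-exhaustion time (0.098 vs 0.109).

Defaults ε1 = 0.6, ε2 = 0.4 are the values used for most reference
simulations; they are otherwise free parameters intended to be calibrated
against in vitro data.

## Numerical method

**Front fixing.**  Each zone is mapped by the affine (Landau) transform onto
the fixed interval ρ ∈ [1, 2]; zone 1 spans (α, β) (or (0, β) after Mg
exhaustion) and zone 2 spans (β, S).  The transform introduces an apparent
advection −ṙ(ρ)·∂rX with ṙ(ρ) interpolating the interface speeds.

**Spatial discretisation.**  Uniform interior nodes per zone (n1, n2;
default 100 each), central differences for both diffusion and advection —
interface Péclet numbers are small throughout, so upwinding is unnecessary.
The radial operator is regularised to (d+1)·∂rr at a node exactly at the
origin.  Boundary nodes are eliminated algebraically from the active
Dirichlet/Robin conditions using 3-point one-sided second-order gradient
stencils, so the ODE state is interior nodes plus α and β.  At a finite-rate
reacting surface the mass-action law plus flux balance give a scalar
quadratic for the surface water value, solved in a cancellation-safe
rationalised form (the diffusive coefficient diverges as a zone thins); in
the non-default advection modes the equation gains a cubic advective term
and is bracketed and solved with Brent's method.

**Time integration.**  Stiff variable-order BDF (`scipy.integrate.solve_ivp`)
with rtol = 1e-7, atol = 1e-9 and a conservative Jacobian sparsity pattern
(per-field tridiagonals plus dense coupling through the interface columns),
which keeps the grouped finite-difference Jacobian cheap.  Each phase ends
at a terminal event located by the integrator's sign-change root finding:
C(β) crossing zero downward (P2_1), or α (resp. β) crossing `stop_radius`.
Halving the tolerances moves the P2_1 event by < 0.1%.

**Singular starts.**  The exact initial state α = β = S = S0 is degenerate.
Integration starts at t = τ0 (default 1e-8): Case 2 in P2_1 with the joint
interface displaced by its leading-order speed −κ/γ0 (ambient water) and
uniform ambient fields; Case 1 in P1_1 with both zones seeded at thickness
δ·S0 (δ = 1e-5), water linear across the hydroxide zone and ambient
elsewhere — the quasi-steady thin-layer profiles.  The P2_1 → P2_2
transition similarly seeds the hydroxide zone at δ·S0 below β with uniform
water at the pre-transition interface value, re-interpolating zone 2 onto
its adjusted extent.  Matched small-time asymptotic expansions are *not*
used; instead the tests verify insensitivity: perturbing τ0 and δ by two
orders of magnitude moves Tα and Tβ by < 0.5%, and mesh doubling moves them
by < 1%.  For very large finite κ the seeded P2_1 state may already have
CO2 exhausted at the interface; the joint phase is then assigned zero
duration, which is its κ → ∞ limit.

**Interface stopping.**  Interfaces are never driven exactly to zero
(1/r^d blows up); an interface reaching `stop_radius` (default 1e-6·S0)
counts as exhausted, truncating O(stop_radius^(d+1)) of volume.  In the
terminal phases the zone-1 diffusion operator conditions like D_W/(h·β)² as
β → 0 and round-off noise in the second differences of the (by then uniform)
water field would stall the integrator; below a thin-zone threshold
(1e-3·S0) the zone-1 water field is therefore frozen at its quasi-steady
limit.  This is exact for the interface dynamics — in those phases β̇
depends only on the CO2 gradient — and affects only the water profile on a
vanishing sliver.

**Advection modes.**  Interface conditions are implemented in a generic
moving-flux form (1−ε)·[(V−ċ)·X − D·∂rX] at an interface moving at ċ.  With
V = v_f (default) the advective parts cancel by no-slip and fluid-flux
continuity, recovering the model's printed conditions; V = 0 and V = v_s
implement the zero-advection and solid-drag alternatives on the same code
path.  The conversion rate at β is mode-independent (C(β) = 0 annihilates
the advective term), so the modes differ mainly in the Mg lifetime:
Tα(fluid) < Tα(none) < Tα(solid), with spreads of a few percent.

## What the benchmark scenarios cover, and what they do not

The presets encode the reference parameter studies: the cylindrical
finite-rate base case (fig2/fig3), the instantaneous-reaction geometry
comparison (fig4), size and porosity sweeps with κ ≈ 0.3 (fig5, fig6), the
rate/porosity contour study (fig7, spherical; ε2 fixed at 0.4 while ε1
varies), the rate sweep (fig8) and the advection comparison (fig9, which
does not state its rate; the base-case κ = 0.0422 is used).  Passing tests
demonstrate internal consistency of the transport-reaction model and
reproduction of its published timescales — they say nothing about phenomena
the model excludes: pitting and surface cracking, chloride chemistry
(MgCl2), pH dynamics, hydrogen gas pockets, carbonate dissolution at the
outer surface, temperature dependence, or genuinely 2D/3D geometry.

## Test problem sizes

Full histories span four decades of time, so the suite sizes its runs
deliberately: the base-case history at n = 100 per zone (with n = 50 and
perturbed-seed variants for the robustness checks), sweeps at n = 40, and
advection/κ comparisons at n = 50 — all inside the < 1% mesh-doubling band
measured for the quantities asserted.  The acceptance script runs at
n = 200.

## Known limitations

* The instantaneous-reaction (Case 1) cylindrical Mg lifetime computed from
  the model equations is Tα ≈ 1.40 (confirmed analytically by the
  quasi-steady Stefan integral Tα = γ0/((1−ε1)·D_W)·∫₀¹ ln(β/α) d(α²) ≈
  1.36), somewhat longer than the "≈ 1" sometimes quoted for this scenario.
* Near complete conversion the CO2 profile forms a logarithmic boundary
  layer at β that the uniform mesh under-resolves; the induced error in Tβ
  is well under the mesh-convergence band because the remaining hydroxide
  volume is negligible by then.
* Concentration fields are not clamped: water may legitimately exceed the
  ambient value near β (production kink), and tiny negative excursions at
  interfaces are floored only where reaction rates would otherwise turn
  imaginary.
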