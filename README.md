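# mgcorrode

Moving-boundary simulation of magnesium (alloy) corrosion in aqueous and
physiological media, for researchers developing biodegradable Mg-based
orthopaedic implants.

A magnesium pellet immersed in water corrodes in two steps,

    Mg + 2 H2O  ->  Mg(OH)2 + H2
    Mg(OH)2 + CO2  ->  MgCO3 + H2O

building two concentric porous product layers — hydroxide between the moving
interfaces r = α(t) and r = β(t), carbonate between β(t) and the outer
surface r = S(t).  Water and dissolved CO2 advect and diffuse through the
pore space of these layers to reach the reaction fronts, so the problem is a
one-dimensional advection–diffusion system with multiple moving boundaries
(a multi-front Stefan problem) in slab, cylindrical or spherical geometry.
Mass conservation alone closes the system: the solid and fluid velocity
fields are algebraic (each of the form const/r^d), and the outer radius obeys

    S^(d+1) = ωα ωβ S0^(d+1) − (ωβ−1) β^(d+1) − ωβ (ωα−1) α^(d+1),

with molar-density ratios ωα = μ_Mg/μ_Mg(OH)2 ≈ 1.8 and
ωβ = μ_Mg(OH)2/μ_MgCO3 ≈ 1.1, so the final carbonate block size
S∞ = S0 (ωα ωβ)^(1/(d+1)) is known a priori.  The Mg–water surface reaction
follows the law of mass action (rate κW², with the instantaneous limit
κ → ∞ as a separate "Case 1"), while CO2 is consumed on contact at β.

The package computes the full corrosion history through its phases — an
early joint-interface transient while the carbonate shell is too thin to
exhaust CO2, growth of the hydroxide layer until the Mg core vanishes at
t = Tα, and the slow carbonation of the remaining hydroxide until it is gone
at t = Tβ — using a front-fixing (Landau) transform per zone, method-of-lines
central differences, stiff BDF integration, and event detection for the
phase transitions.  Sweep utilities reproduce the characteristic parameter
dependencies, e.g. Tβ ∝ S0²/(1−ε2) where ε2 is the carbonate solid fraction.

## Worked example

```python
import mgcorrode as mg

params, _ = mg.preset("fig3")          # cylindrical base case: eps1=0.6,
                                       # eps2=0.4, kappa=0.07/1.66, S0=1
res = mg.simulate(params, mg.SolverConfig(n1=100, n2=100))
print(f"T_ab    = {res.T_ab:.4f}")
print(f"T_alpha = {res.T_alpha:.2f}")
print(f"T_beta  = {res.T_beta:.1f}")
print(f"S_inf   = {res.S_inf:.4f}")
```

prints

```
T_ab    = 0.0980
T_alpha = 33.16
T_beta  = 1270.7
S_inf   = 1.4071
```

Times are dimensionless; one unit is 24·S0*²/DC hours — about 14.5 h for the
tabulated CO2 diffusivity and a 1 cm reference length
(`mg.time_unit_hours(mg.PhysicalParameters())`).  Reading the output: CO2 is
first exhausted at the joint interface almost immediately (T_ab ≈ 0.1, ~1.4
h), the 1 cm Mg core survives for Tα ≈ 33 units (~20 days), and the
protective hydroxide takes Tβ ≈ 1271 units (~766 days) to carbonate fully,
by which point the block has swollen to S∞ ≈ 1.41 cm of MgCO3.  The
hydroxide layer first *grows* outward (β peaks near 1.2) because each
converted Mg mole occupies ωα ≈ 1.8 times the volume.

The same run from the shell, plus a figure:

```sh
mgcorrode run --preset fig3 --n 100 --out results/
mgcorrode plot results/trajectory.csv
```

`mgcorrode sweep`, `mgcorrode compare-advection` and `mgcorrode reproduce`
drive the parameter studies; YAML configuration files (see
`mgcorrode.io.load_config`) accept either physical (cm/g/day) or
dimensionless parameter blocks.

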