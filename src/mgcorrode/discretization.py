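"""Method-of-lines spatial kernel on front-fixed zone meshes.

Each moving zone (alpha, beta) and (beta, S) is mapped by the affine Landau
transform onto the fixed interval rho in [1, 2]:

    r(rho, t) = inner(t) + (rho - 1) * (outer(t) - inner(t)),

so the grid never moves in rho and the mesh motion appears as an extra
advection term -rdot(rho) * dX/dr.  Spatial derivatives use central
differences (second order); boundary nodes are eliminated algebraically from
the active Dirichlet/Robin interface conditions using 3-point one-sided
second-order gradient stencils, so the ODE state consists of interior nodes
plus the interface positions only.

Interface conditions are applied in a generic moving-flux form: at an
interface moving at speed cdot with advective species velocity V, the species
flux is (1 - eps) * ((V - cdot) * X - D * dX/dr).  With V equal to the fluid
velocity this reduces exactly to the model's interface conditions (the
advective parts cancel by no-slip / fluid-flux continuity); with V = 0 or
V = vs it implements the alternative advection assumptions on a single code
path.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.optimize import brentq

from .conservation import velocity_fields
from .parameters import DimensionlessParameters
from .state import Phase, PhaseState

__all__ = [
    "ZoneMesh",
    "InterfaceRates",
    "DegenerateZoneError",
    "transform_rhs",
    "interface_rates",
    "assemble_phase_rhs",
    "MIN_ZONE_WIDTH",
]

#: Zones thinner than this (times max(1, S0)) cannot be meshed; the simulator
#: must seed them at finite thickness instead.
MIN_ZONE_WIDTH = 1e-12


class DegenerateZoneError(RuntimeError):
    """Raised when a zone is too thin for the fixed-grid transform."""


@dataclass
class ZoneMesh:
    """Uniform mesh on rho in [1, 2] for one zone, with boundary values.

    ``values`` has length n + 2 and includes the two boundary nodes.
    """

    n: int
    inner: float
    outer: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("mesh needs at least one interior node")
        if len(self.values) != self.n + 2:
            raise ValueError("values must include the two boundary nodes")

    @property
    def h(self) -> float:
        return 1.0 / (self.n + 1)

    @property
    def rho(self) -> np.ndarray:
        return np.linspace(1.0, 2.0, self.n + 2)

    @property
    def width(self) -> float:
        return self.outer - self.inner

    def r(self) -> np.ndarray:
        """Physical node positions (including boundaries)."""
        return self.inner + (self.rho - 1.0) * self.width


def transform_rhs(mesh: ZoneMesh, inner_dot: float, outer_dot: float,
                  D: float, V, d: int, upwind: bool = False) -> np.ndarray:
    """Time derivatives dX/dt at fixed rho for the interior nodes.

    Implements the advection-diffusion operator
        dX/dt = -(V - rdot) dX/dr + (D / r**d) d/dr (r**d dX/dr)
    with rdot the mesh velocity of the Landau map.  ``V`` is a callable of r
    or an array at the interior nodes.  At a node sitting exactly at r = 0
    the radial operator is regularised to D * (d+1) * d2X/dr2.

    The advective term uses central differences by default (interface Peclet
    numbers are small throughout); ``upwind`` switches it to first-order
    upwinding for robustness experiments.
    """
    L = mesh.width
    if L < MIN_ZONE_WIDTH * max(1.0, abs(mesh.outer)):
        raise DegenerateZoneError(
            f"zone width {L:g} below meshable minimum; seed the zone instead")
    h = mesh.h
    X = mesh.values
    rho_i = mesh.rho[1:-1]
    r_i = mesh.inner + (rho_i - 1.0) * L

    dX_drho = (X[2:] - X[:-2]) / (2.0 * h)
    d2X_drho2 = (X[2:] - 2.0 * X[1:-1] + X[:-2]) / h**2
    dX_dr = dX_drho / L
    d2X_dr2 = d2X_drho2 / L**2

    rdot = inner_dot + (rho_i - 1.0) * (outer_dot - inner_dot)
    v = V(r_i) if callable(V) else np.asarray(V, dtype=float)
    adv_vel = v - rdot
    if upwind:
        back = (X[1:-1] - X[:-2]) / (h * L)
        fwd = (X[2:] - X[1:-1]) / (h * L)
        adv_grad = np.where(adv_vel > 0.0, back, fwd)
    else:
        adv_grad = dX_dr

    diff = D * d2X_dr2
    if d:
        at_origin = r_i == 0.0
        if np.any(at_origin):
            curv = np.zeros_like(r_i)
            curv[~at_origin] = d / r_i[~at_origin] * dX_dr[~at_origin]
            diff = D * (d2X_dr2 + curv)
            diff[at_origin] = D * (d + 1) * d2X_dr2[at_origin]
        else:
            diff = D * (d2X_dr2 + d / r_i * dX_dr)
    return -adv_vel * adv_grad + diff


@dataclass(frozen=True)
class InterfaceRates:
    """Interface speeds and the boundary values implied by the active conditions."""

    alpha_dot: float
    beta_dot: float
    boundary_values: dict


def _grad_in(xb: float, x1: float, x2: float, h: float, L: float) -> float:
    """Second-order one-sided d/dr at the inner (rho = 1) boundary."""
    return (-3.0 * xb + 4.0 * x1 - x2) / (2.0 * h * L)


def _grad_out(xb: float, xn: float, xnm1: float, h: float, L: float) -> float:
    """Second-order one-sided d/dr at the outer (rho = 2) boundary."""
    return (3.0 * xb - 4.0 * xn + xnm1) / (2.0 * h * L)


def _stable_quad_root(a: float, g3: float, gb: float) -> float:
    """Non-negative root of a*W**2 + g3*W - gb = 0 for a, g3 > 0, gb >= 0.

    Uses the rationalised form to avoid cancellation when g3 >> a (razor-thin
    zones make the diffusive coefficient huge).
    """
    if gb <= 0.0:
        return 0.0
    return 2.0 * gb / (g3 + np.sqrt(g3 * g3 + 4.0 * a * gb))


def _kinetic_boundary_value(kin2: float, cadv: float, kappa: float, gamma0: float,
                            gdiff: float, b: float) -> float:
    """Surface water value W at a finite-rate reacting interface.

    Solves  (1-eps)[cadv*xdot*W - D*dW/dr] = kin2*gamma0*xdot  with the law of
    mass action xdot = -kappa*W**2/gamma0 and the one-sided gradient
    dW/dr = (-3W + b)/(2hL) folded into ``gdiff`` = (1-eps)*D/(2hL).
    ``kin2`` is the stoichiometric factor multiplying gamma0*xdot (2 at the Mg
    surface, omega_alpha*gamma1/gamma0 ... callers pass the full factor) and
    ``cadv`` the advective coefficient (0 in fluid mode by no-slip).
    """
    if b <= 0.0:
        return 0.0
    if cadv == 0.0:
        # kin2*kappa*W^2 + 3*gdiff*W - gdiff*b = 0
        return _stable_quad_root(kin2 * kappa, 3.0 * gdiff, gdiff * b)

    def F(W: float) -> float:
        xdot = -kappa * W * W / gamma0
        # cadv term uses the zone fluid fraction already folded into gdiff's
        # companion coefficient; cadv passed pre-multiplied by (1-eps).
        return cadv * xdot * W - gdiff * (-3.0 * W + b) - kin2 * gamma0 * xdot

    # F(0) < 0 (inward diffusive supply), F grows like +W^3 or +W^2.
    ub = max(1.0, b / 3.0) * 2.0
    while F(ub) < 0.0:
        ub *= 2.0
        if ub > 1e6:
            raise RuntimeError("failed to bracket reacting-interface value")
    return brentq(F, 0.0, ub, xtol=1e-15, rtol=1e-14)


def interface_rates(state: PhaseState, p: DimensionlessParameters,
                    mode: str = "fluid") -> InterfaceRates:
    """Interface speeds and boundary concentrations for the active phase.

    Phase 2.1 (joint interface): the Mg surface speed follows the law of mass
    action beta_dot = -kappa*W2(beta)**2/gamma0 with Robin fluxes supplying
    one net H2O and one CO2 per converted Mg.  Phases 1.1/2.2: water is
    exhausted (Case 1) or reacts at finite rate (Case 2) at alpha, while at
    beta CO2 vanishes, water is continuous, and the flux jumps set beta_dot
    relative to the local solid velocity.  Phases 1.2/2.3 drop the alpha
    conditions in favour of symmetry at r = 0.  The outer surface always
    carries ambient W2 = C2 = 1.
    """
    phase = state.phase
    if phase is Phase.P2_1:
        return _rates_joint(state, p, mode)
    if phase.has_zone1:
        return _rates_two_zone(state, p, mode)
    raise ValueError(f"no interface conditions for phase {phase!r}")


def _rates_joint(state: PhaseState, p: DimensionlessParameters,
                 mode: str) -> InterfaceRates:
    W2, C2 = state.W2, state.C2
    n2 = len(W2)
    h2 = 1.0 / (n2 + 1)
    L2 = state.S - state.beta
    e2 = p.eps2
    wa, wb = p.omega_alpha, p.omega_beta

    bW = 4.0 * W2[0] - W2[1]
    bC = 4.0 * C2[0] - C2[1]
    gdiff_W = (1.0 - e2) * p.DW / (2.0 * h2 * L2)

    # Advective coefficient (V2(beta) - beta_dot), proportional to beta_dot.
    if mode == "fluid":
        cj = 0.0           # no-slip: vf2(beta) = beta_dot
    elif mode == "none":
        cj = -1.0
    elif mode == "solid":
        cj = -(wa * wb)    # vs2(beta) - beta_dot = -(wa*wb-1)bd - bd
    else:
        raise ValueError(f"unknown advection mode {mode!r}")

    kin_W = wa * p.gamma1 / p.gamma0  # water flux factor per gamma0*beta_dot
    Wb = _kinetic_boundary_value(
        kin_W, (1.0 - e2) * cj, p.kappa, p.gamma0, gdiff_W, bW)
    beta_dot = -p.kappa * Wb * Wb / p.gamma0

    # CO2 Robin condition, linear in the boundary value.
    gC = (1.0 - e2) / (2.0 * h2 * L2)
    denom = (1.0 - e2) * cj * beta_dot + 3.0 * gC
    Cb = (p.gamma2 * wa * beta_dot + gC * bC) / denom

    return InterfaceRates(
        alpha_dot=beta_dot, beta_dot=beta_dot,
        boundary_values={"W2_beta": Wb, "C2_beta": Cb, "W2_S": 1.0, "C2_S": 1.0},
    )


def _rates_two_zone(state: PhaseState, p: DimensionlessParameters,
                    mode: str) -> InterfaceRates:
    phase = state.phase
    W1, W2, C2 = state.W1, state.W2, state.C2
    n1, n2 = len(W1), len(W2)
    h1 = 1.0 / (n1 + 1)
    h2 = 1.0 / (n2 + 1)
    alpha, beta, S = state.alpha, state.beta, state.S
    inner1 = 0.0 if phase.alpha_is_zero else alpha
    L1 = beta - inner1
    L2 = S - beta
    e1, e2, d = p.eps1, p.eps2, p.d
    wa = p.omega_alpha
    DW = p.DW

    b1 = 4.0 * W1[0] - W1[1]          # inner one-sided companion, zone 1
    bW1 = 4.0 * W1[-1] - W1[-2]       # outer one-sided companion, zone 1
    bW2 = 4.0 * W2[0] - W2[1]         # inner one-sided companion, zone 2
    bC = 4.0 * C2[0] - C2[1]

    # --- alpha interface -----------------------------------------------------
    if phase.alpha_is_zero:
        alpha_dot = 0.0
        W1_alpha = b1 / 3.0            # zero-gradient ghost value at r = 0
    elif p.instantaneous:
        # Case 1: water exhausted at the Mg surface; Stefan condition.
        W1_alpha = 0.0
        dW1_a = _grad_in(0.0, W1[0], W1[1], h1, L1)
        alpha_dot = -(1.0 - e1) * DW * dW1_a / (2.0 * p.gamma0)
    else:
        if mode == "fluid":
            ca = 0.0                    # no-slip: vf1(alpha) = alpha_dot
        elif mode == "none":
            ca = -1.0
        else:
            ca = -wa                    # vs1(alpha) - alpha_dot
        gdiff1 = (1.0 - e1) * DW / (2.0 * h1 * L1)
        W1_alpha = _kinetic_boundary_value(
            2.0, (1.0 - e1) * ca, p.kappa, p.gamma0, gdiff1, b1)
        alpha_dot = -p.kappa * W1_alpha**2 / p.gamma0

    # --- beta interface ------------------------------------------------------
    # CO2 is exhausted at beta; its gradient fixes the net conversion rate
    # R = beta_dot - vs1(beta) regardless of advection mode (C2(beta) = 0).
    dC_b = _grad_in(0.0, C2[0], C2[1], h2, L2)
    R = -(1.0 - e2) * dC_b / p.gamma2
    if phase.alpha_is_zero:
        vs1_b = 0.0
    else:
        vs1_b = -(wa - 1.0) * alpha_dot * (alpha / beta) ** d
    beta_dot = R + vs1_b

    # Advective interface velocities for the water-flux jump.
    if mode == "fluid":
        a1 = a2 = 0.0                  # cancels by fluid-flux continuity
    else:
        vel = velocity_fields(alpha if not phase.alpha_is_zero else 0.0,
                              beta, alpha_dot, beta_dot, phase, p)
        if mode == "none":
            V1b = V2b = 0.0
        else:
            V1b = float(vel.vs1(np.array([beta]))[0])
            V2b = float(vel.vs2(np.array([beta]))[0])
        a1 = (1.0 - e1) * (V1b - beta_dot)
        a2 = (1.0 - e2) * (V2b - beta_dot)

    g1 = (1.0 - e1) * DW / (2.0 * h1 * L1)
    g2 = (1.0 - e2) * DW / (2.0 * h2 * L2)
    lhs = (a2 - a1) + 3.0 * g2 + 3.0 * g1
    rhs = -p.gamma1 * R + g2 * bW2 + g1 * bW1
    # Floor at zero: water is non-negative.  Transiently negative values can
    # appear in trial steps of the stiff solver probing unphysical states.
    W_beta = max(rhs / lhs, 0.0)

    return InterfaceRates(
        alpha_dot=alpha_dot, beta_dot=beta_dot,
        boundary_values={
            "W1_alpha": W1_alpha, "W_beta": W_beta, "C2_beta": 0.0,
            "W2_S": 1.0, "C2_S": 1.0,
        },
    )


def assemble_phase_rhs(state: PhaseState, p: DimensionlessParameters,
                       mode: str = "fluid", freeze_zone1: bool = False,
                       upwind: bool = False):
    """Full time-derivative of the method-of-lines state.

    Returns ``(dW1, dW2, dC2, alpha_dot, beta_dot)`` with ``dW1`` ``None`` in
    phase 2.1.  Combines the interface rates, the exact velocity fields, the
    chain-rule outer-surface speed and the front-fixed transport operator.
    ``freeze_zone1`` holds the zone-1 water field at its quasi-steady limit
    (dW1 = 0), used by the simulator once the hydroxide layer is too thin for
    its diffusion operator to be well conditioned.
    """
    from .conservation import outer_radius_rate  # local to avoid cycle noise

    phase = state.phase
    rates = interface_rates(state, p, mode)
    ad, bd = rates.alpha_dot, rates.beta_dot
    bv = rates.boundary_values
    S = state.S

    vel = velocity_fields(0.0 if phase.joint_interface else state.alpha,
                          state.beta, ad, bd, phase, p)
    Sd = outer_radius_rate(state.alpha, state.beta, S, ad, bd, p,
                           include_alpha=phase in (Phase.P1_1, Phase.P2_2))

    if phase.joint_interface:
        Wb, Cb = bv["W2_beta"], bv["C2_beta"]
        dW1 = None
    elif freeze_zone1:
        Wb, Cb = bv["W_beta"], bv["C2_beta"]
        dW1 = np.zeros_like(state.W1)
    else:
        Wb, Cb = bv["W_beta"], bv["C2_beta"]
        inner1 = 0.0 if phase.alpha_is_zero else state.alpha
        inner1_dot = 0.0 if phase.alpha_is_zero else ad
        m1 = ZoneMesh(n=state.n1, inner=inner1, outer=state.beta,
                      values=np.concatenate(([bv["W1_alpha"]], state.W1, [Wb])))
        dW1 = transform_rhs(m1, inner1_dot, bd, p.DW,
                            vel.advective(1, mode), p.d, upwind=upwind)

    m2W = ZoneMesh(n=state.n2, inner=state.beta, outer=S,
                   values=np.concatenate(([Wb], state.W2, [bv["W2_S"]])))
    m2C = ZoneMesh(n=state.n2, inner=state.beta, outer=S,
                   values=np.concatenate(([Cb], state.C2, [bv["C2_S"]])))
    V2 = vel.advective(2, mode)
    dW2 = transform_rhs(m2W, bd, Sd, p.DW, V2, p.d, upwind=upwind)
    dC2 = transform_rhs(m2C, bd, Sd, 1.0, V2, p.d, upwind=upwind)

    # Non-finite values are returned as-is: the stiff solver treats them as a
    # failed Newton iteration and shrinks the step.
    return dW1, dW2, dC2, ad, bd
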