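"""Closed-form consequences of mass conservation.

Because the geometry is ideal (slab / cylinder / sphere) and the solid
fractions are constant, integrating the continuity equations gives the solid
and fluid velocity fields in each zone in closed form, every term of the form
(constant)/r**d.  Total magnesium conservation likewise fixes the outer
radius S algebraically from the interface positions, and hence the final
carbonate block size a priori:

    S**(d+1) = wa*wb*S0**(d+1) - (wb-1)*beta**(d+1) - wb*(wa-1)*alpha**(d+1)
    S_inf    = S0 * (wa*wb)**(1/(d+1))

with wa = omega_alpha, wb = omega_beta.  The simulator never integrates S as
an ODE; it is always recomputed from this identity, which makes the global
magnesium balance exact to round-off and is used as a runtime invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .parameters import DimensionlessParameters
from .state import Phase

__all__ = [
    "VelocityField",
    "velocity_fields",
    "outer_radius",
    "outer_radius_rate",
    "final_size",
    "magnesium_balance_residual",
]


@dataclass(frozen=True)
class VelocityField:
    """Radial solid/fluid velocities per zone for one phase.

    Each entry is a vectorised callable of radius.  Zone-1 fields are defined
    (identically zero) even when the zone is absent or static so that callers
    can evaluate them unconditionally.
    """

    vs1: Callable[[np.ndarray], np.ndarray]
    vs2: Callable[[np.ndarray], np.ndarray]
    vf1: Callable[[np.ndarray], np.ndarray]
    vf2: Callable[[np.ndarray], np.ndarray]
    valid_phase: Phase

    def advective(self, zone: int, mode: str) -> Callable[[np.ndarray], np.ndarray]:
        """Advective velocity used for species transport in ``zone``.

        ``mode`` selects the transport assumption: ``fluid`` (porous-media
        pore flow, the model default), ``none`` (pure diffusion) or ``solid``
        (species dragged with the crystal structure).
        """
        if mode == "none":
            return _zero
        if mode == "fluid":
            return self.vf1 if zone == 1 else self.vf2
        if mode == "solid":
            return self.vs1 if zone == 1 else self.vs2
        raise ValueError(f"unknown advection mode {mode!r}")


def _zero(r):
    return np.zeros_like(np.asarray(r, dtype=float))


def _over_rd(coeff: float, d: int) -> Callable[[np.ndarray], np.ndarray]:
    if coeff == 0.0:
        return _zero

    def f(r):
        r = np.asarray(r, dtype=float)
        return coeff / r**d if d else np.full_like(r, coeff)

    return f


def velocity_fields(alpha: float, beta: float, alpha_dot: float, beta_dot: float,
                    phase: Phase, p: DimensionlessParameters) -> VelocityField:
    """Exact solid/fluid velocity fields for the given phase.

    The no-slip condition makes vf1(alpha) = alpha_dot whenever zone 1 exists,
    and vf2(beta) = beta_dot at the joint interface of phase 2.1.  After Mg
    exhaustion zone 1 is static (vs1 = vf1 = 0).
    """
    if not 0.0 <= alpha <= beta:
        raise ValueError(f"need 0 <= alpha <= beta, got {alpha}, {beta}")
    wa, wb, d = p.omega_alpha, p.omega_beta, p.d
    e1, e2 = p.eps1, p.eps2

    if phase in (Phase.P1_1, Phase.P2_2):
        a_flux = alpha_dot * alpha**d
        b_flux = beta_dot * beta**d
        vs1 = _over_rd(-(wa - 1.0) * a_flux, d)
        vs2 = _over_rd(-(wb * (wa - 1.0) * a_flux + (wb - 1.0) * b_flux), d)
        vf1 = _over_rd(a_flux, d)
        vf2 = _over_rd(((1.0 - e1) * a_flux - (e2 - e1) * b_flux) / (1.0 - e2), d)
    elif phase in (Phase.P1_2, Phase.P2_3):
        b_flux = beta_dot * beta**d
        vs1 = _zero
        vf1 = _zero
        vs2 = _over_rd(-(wb - 1.0) * b_flux, d)
        vf2 = _over_rd(-(e2 - e1) * b_flux / (1.0 - e2), d)
    elif phase is Phase.P2_1:
        b_flux = beta_dot * beta**d
        vs1 = _zero
        vf1 = _zero
        vs2 = _over_rd(-(wa * wb - 1.0) * b_flux, d)
        vf2 = _over_rd(b_flux, d)
    else:
        raise ValueError(f"no velocity fields defined for phase {phase!r}")
    return VelocityField(vs1=vs1, vs2=vs2, vf1=vf1, vf2=vf2, valid_phase=phase)


def outer_radius(alpha: float, beta: float, p: DimensionlessParameters) -> float:
    """Algebraic outer radius implied by magnesium conservation."""
    d1 = p.d + 1
    wa, wb = p.omega_alpha, p.omega_beta
    radicand = (wa * wb * p.S0**d1
                - (wb - 1.0) * beta**d1
                - wb * (wa - 1.0) * alpha**d1)
    if radicand < 0.0:
        raise ValueError(
            f"inconsistent interface positions alpha={alpha}, beta={beta}: "
            f"negative conserved volume {radicand}")
    return radicand ** (1.0 / d1)


def outer_radius_rate(alpha: float, beta: float, S: float,
                      alpha_dot: float, beta_dot: float,
                      p: DimensionlessParameters,
                      include_alpha: bool = True) -> float:
    """dS/dt by the chain rule on the conservation identity.

    ``include_alpha`` must be False in phases where alpha is pinned at zero
    (its stoichiometric term is absent, which matters for d = 0 where
    alpha**d = 1 even at alpha = 0).
    """
    wa, wb, d = p.omega_alpha, p.omega_beta, p.d
    num = (wb - 1.0) * beta**d * beta_dot
    if include_alpha:
        num += wb * (wa - 1.0) * alpha**d * alpha_dot
    return -num / S**d


def final_size(p: DimensionlessParameters) -> float:
    """Final carbonate block size S_inf = S0 * (wa*wb)**(1/(d+1))."""
    return p.S0 * (p.omega_alpha * p.omega_beta) ** (1.0 / (p.d + 1))


def magnesium_balance_residual(state, p: DimensionlessParameters) -> float:
    """Absolute residual of the global magnesium mole balance.

    Zero in exact arithmetic in every phase: Mg moles in the core plus those
    bound in each product layer equal the initial core content.  ``state`` is
    any object with ``alpha``, ``beta`` and ``S`` attributes.
    """
    return mole_balance(state.alpha, state.beta, state.S, p)


def mole_balance(alpha: float, beta: float, S: float,
                 p: DimensionlessParameters) -> float:
    d1 = p.d + 1
    wa, wb = p.omega_alpha, p.omega_beta
    total = (wa * wb * alpha**d1
             + wb * (beta**d1 - alpha**d1)
             + (S**d1 - beta**d1))
    return abs(total - wa * wb * p.S0**d1)
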