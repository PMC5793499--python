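"""Physical and dimensionless parameter sets for the Mg corrosion model.

The model tracks a magnesium pellet corroding in aqueous media:
Mg + 2 H2O -> Mg(OH)2 + H2 at the inner interface r = alpha(t), and
Mg(OH)2 + CO2 -> MgCO3 + H2O at the middle interface r = beta(t).  The
hydroxide and carbonate products form concentric porous layers whose outer
surface r = S(t) is exposed to ambient water and CO2.

Dimensional inputs (cm / g / day units throughout) are collected in
:class:`PhysicalParameters`; :func:`nondimensionalize` maps them to the
:class:`DimensionlessParameters` actually integrated.  Lengths are scaled by
a reference size ``S0_star`` and time by the CO2 diffusion timescale
``S0_star**2 / DC_dim``, so concentrations relax on O(1) dimensionless times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "PhysicalParameters",
    "DimensionlessParameters",
    "derive_molar_ratios",
    "nondimensionalize",
    "time_unit_hours",
    "preset",
    "PRESET_NAMES",
]


def _require_positive(name: str, value: float, allow_inf: bool = False) -> None:
    if allow_inf and math.isinf(value) and value > 0:
        return
    if not (value > 0 and math.isfinite(value)):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


def _require_fraction(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {value!r}")


@dataclass(frozen=True)
class PhysicalParameters:
    """Dimensional constants of the corrosion system (cm / g / day units).

    Defaults are standard literature values for pure Mg corroding in a
    physiological aqueous environment.  The Mg-water surface rate ``k``
    (cm^4 / (g day)) may be ``math.inf``, selecting the instantaneous-reaction
    limit (Case 1) in which water is fully exhausted at the Mg surface.

    Densities ``rho1``/``rho2`` are layer densities inclusive of the void
    fraction; zone 0 (pure Mg) is fully solid.
    """

    DW_dim: float = 2.85    # H2O diffusivity, cm^2/day
    DC_dim: float = 1.66    # CO2 diffusivity, cm^2/day
    M0: float = 24.3        # molar mass Mg, g/mol
    M1: float = 58.3        # molar mass Mg(OH)2, g/mol
    M2: float = 84.3        # molar mass MgCO3, g/mol
    MW: float = 18.0        # molar mass H2O, g/mol
    MC: float = 44.0        # molar mass CO2, g/mol
    rho0: float = 1.74      # Mg density, g/cm^3
    rho1: float = 2.34      # Mg(OH)2 layer density, g/cm^3
    rho2: float = 2.96      # MgCO3 layer density, g/cm^3
    W0_star: float = 1.0    # ambient water mass concentration, g/cm^3
    C0_star: float = 0.0011  # ambient CO2 mass concentration, g/cm^3
    k: float = math.inf     # Mg-water reaction rate, cm^4/(g day); inf = Case 1
    eps1: float = 0.6       # solid fraction of the Mg(OH)2 layer
    eps2: float = 0.4       # solid fraction of the MgCO3 layer
    S0_star: float = 1.0    # reference length, cm
    S0_dim: float = 1.0     # initial pellet half-thickness / radius, cm

    def __post_init__(self) -> None:
        for name in ("DW_dim", "DC_dim", "M0", "M1", "M2", "MW", "MC",
                     "rho0", "rho1", "rho2", "W0_star", "C0_star",
                     "S0_star", "S0_dim"):
            _require_positive(name, getattr(self, name))
        _require_positive("k", self.k, allow_inf=True)
        _require_fraction("eps1", self.eps1)
        _require_fraction("eps2", self.eps2)

    @property
    def reaction_instantaneous(self) -> bool:
        return math.isinf(self.k)


@dataclass(frozen=True)
class DimensionlessParameters:
    """Dimensionless constants of the system actually solved.

    ``gamma0``..``gamma2`` are interface mass-flux coefficients, ``kappa`` the
    surface reaction rate (``math.inf`` selects Case 1), ``omega_alpha`` /
    ``omega_beta`` the molar-density (volume expansion) ratios of the
    Mg -> Mg(OH)2 and Mg(OH)2 -> MgCO3 conversions, and ``d`` the geometry
    index (0 slab, 1 cylinder, 2 sphere).
    """

    DW: float
    gamma0: float
    gamma1: float
    gamma2: float
    kappa: float
    omega_alpha: float
    omega_beta: float
    eps1: float
    eps2: float
    S0: float = 1.0
    d: int = 1

    def __post_init__(self) -> None:
        for name in ("DW", "gamma0", "gamma1", "gamma2",
                     "omega_alpha", "omega_beta", "S0"):
            _require_positive(name, getattr(self, name))
        _require_positive("kappa", self.kappa, allow_inf=True)
        _require_fraction("eps1", self.eps1)
        _require_fraction("eps2", self.eps2)
        if self.d not in (0, 1, 2):
            raise ValueError(f"geometry index d must be 0, 1 or 2, got {self.d!r}")

    @property
    def instantaneous(self) -> bool:
        """True in the instantaneous-reaction limit (Case 1)."""
        return math.isinf(self.kappa)

    @property
    def case(self) -> int:
        return 1 if self.instantaneous else 2

    def replace(self, **changes) -> "DimensionlessParameters":
        return replace(self, **changes)


def derive_molar_ratios(phys: PhysicalParameters) -> tuple[float, float]:
    """Molar-density ratios (omega_alpha, omega_beta) of the two conversions.

    omega_alpha = mu0/mu1 and omega_beta = mu1/mu2 with molar densities
    mu_i = rho_i / M_i; omega > 1 means the product layer occupies more volume
    than the reactant it replaces.
    """
    mu0 = phys.rho0 / phys.M0
    mu1 = phys.rho1 / phys.M1
    mu2 = phys.rho2 / phys.M2
    return mu0 / mu1, mu1 / mu2


def nondimensionalize(phys: PhysicalParameters, d: int = 1) -> DimensionlessParameters:
    """Map dimensional parameters to the dimensionless set.

    Scales: length by ``S0_star``, time by ``S0_star**2 / DC_dim``, water by
    ``W0_star`` and CO2 by ``C0_star``.  An infinite reaction rate maps to an
    infinite ``kappa`` (Case 1 flag, never a large float).
    """
    omega_alpha, omega_beta = derive_molar_ratios(phys)
    kappa = math.inf if phys.reaction_instantaneous else (
        phys.S0_star * phys.W0_star * phys.k / phys.DC_dim)
    return DimensionlessParameters(
        DW=phys.DW_dim / phys.DC_dim,
        gamma0=phys.MW * phys.rho0 / (phys.M0 * phys.W0_star),
        gamma1=phys.MW * phys.rho1 / (phys.M1 * phys.W0_star),
        gamma2=phys.MC * phys.rho1 / (phys.M1 * phys.C0_star),
        kappa=kappa,
        omega_alpha=omega_alpha,
        omega_beta=omega_beta,
        eps1=phys.eps1,
        eps2=phys.eps2,
        S0=phys.S0_dim / phys.S0_star,
        d=d,
    )


def time_unit_hours(phys: PhysicalParameters) -> float:
    """Hours represented by one dimensionless time unit: 24 * S0_star**2 / DC."""
    return 24.0 * phys.S0_star**2 / phys.DC_dim


# Benchmark scenario presets.  All share the tabulated dimensionless constants
# (including the tabulated DW = 1.5625, which differs slightly from the
# 2.85/1.66 diffusivity ratio; see docs/methods.md) and vary geometry, solid
# fractions and reaction rate.
_TABLE_CONSTANTS = dict(
    DW=1.5625,
    gamma0=1.2889,
    gamma1=0.7225,
    gamma2=1605.5,
    omega_alpha=1.8,
    omega_beta=1.1,
)

# The finite-rate base case uses k = 0.07 cm^4/(g day), i.e. kappa =
# 0.07/1.66 ~ 0.0422 (commonly quoted rounded as "kappa ~ 0.04").
_KAPPA_BASE = 0.07 / 1.66

_PRESETS: dict[str, dict] = {
    # Finite-rate base case: cylinder.
    "fig2": dict(d=1, eps1=0.6, eps2=0.4, kappa=_KAPPA_BASE, S0=1.0),
    # Same run as fig2; kept as an alias for the profile-snapshot scenario.
    "fig3": dict(d=1, eps1=0.6, eps2=0.4, kappa=_KAPPA_BASE, S0=1.0),
    # Instantaneous reaction (Case 1), cylinder by default.
    "fig4": dict(d=1, eps1=0.6, eps2=0.4, kappa=math.inf, S0=1.0),
    # Initial-size sweeps use kappa ~ 0.3 (k = 0.5 cm^4/(g day)).
    "fig5": dict(d=1, eps1=0.6, eps2=0.4, kappa=0.3, S0=1.0),
    # Porosity sweeps.
    "fig6": dict(d=1, eps1=0.6, eps2=0.4, kappa=0.3, S0=1.0),
    # Reaction-rate / porosity contour study, spherical.
    "fig7": dict(d=2, eps1=0.6, eps2=0.4, kappa=0.3, S0=1.0),
    # Reaction-rate sweep, cylinder.
    "fig8": dict(d=1, eps1=0.6, eps2=0.4, kappa=0.3, S0=1.0),
    # Advection-mode comparison; base case parameters.
    "fig9": dict(d=1, eps1=0.6, eps2=0.4, kappa=_KAPPA_BASE, S0=1.0),
}

PRESET_NAMES: tuple[str, ...] = tuple(sorted(_PRESETS))

# Solver settings suited to each scenario (merged over SolverConfig defaults).
_PRESET_SOLVER: dict[str, dict] = {name: {} for name in _PRESETS}


def preset(name: str, **overrides) -> tuple[DimensionlessParameters, dict]:
    """Return (parameters, solver-option dict) for a named benchmark scenario.

    ``overrides`` replace individual dimensionless fields (e.g. ``d=2`` to run
    the fig4 scenario in spherical geometry).
    """
    try:
        spec_kwargs = dict(_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
    spec_kwargs.update(overrides)
    params = DimensionlessParameters(**_TABLE_CONSTANTS, **spec_kwargs)
    return params, dict(_PRESET_SOLVER[name])
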