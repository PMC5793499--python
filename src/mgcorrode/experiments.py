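"""Parameter studies: sweeps over geometry, size, porosity and reaction rate.

The headline outputs of the model are the degradation timescales: T_ab (CO2
first exhausted at the joint interface, finite-rate case only), T_alpha (Mg
core gone) and T_beta (hydroxide layer gone, leaving the final carbonate
block).  These respond to the free parameters in characteristic ways — e.g.
T_beta grows like S0**2 / (1 - eps2) because the slow CO2 supply through the
carbonate layer is rate limiting — and the sweep helpers here reproduce those
studies and fit the power laws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .parameters import DimensionlessParameters
from .simulator import SimulationResult, SolverConfig, simulate

__all__ = ["SweepResult", "sweep", "scaling_exponent", "compare_advection_modes"]

logger = logging.getLogger("mgcorrode")

_SWEEPABLE = ("S0", "eps1", "eps2", "kappa", "d")


@dataclass
class SweepResult:
    """Degradation timescales across a one-parameter grid.

    ``records`` holds one dict per swept value with keys ``value``, ``T_ab``,
    ``T_alpha``, ``T_beta``, ``S_inf`` and ``error`` (None for converged
    runs).  Failed runs are recorded, not fatal.
    """

    parameter_name: str
    values: np.ndarray
    records: list
    base: DimensionlessParameters

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def successful(self) -> list:
        return [r for r in self.records if r["error"] is None]


def sweep(parameter_name: str, values: Sequence, base: DimensionlessParameters,
          cfg: Optional[SolverConfig] = None, until: str = "end") -> SweepResult:
    """Run one simulation per value of a single swept parameter.

    ``until="T_alpha"`` truncates each run once the Mg core is gone — much
    cheaper when T_beta is not needed (kappa and eps1 studies).
    """
    if parameter_name not in _SWEEPABLE:
        raise ValueError(
            f"cannot sweep {parameter_name!r}; choose one of {_SWEEPABLE}")
    if cfg is None:
        cfg = SolverConfig()
    records = []
    for value in values:
        params = base.replace(**{parameter_name: value if parameter_name != "d"
                                 else int(value)})
        rec = {"value": value, "T_ab": None, "T_alpha": None,
               "T_beta": None, "S_inf": None, "error": None}
        try:
            res = simulate(params, cfg, until=until)
        except Exception as exc:  # individual failures recorded, sweep continues
            logger.warning("sweep %s=%g failed: %s", parameter_name, value, exc)
            rec["error"] = str(exc)
        else:
            rec.update(T_ab=res.T_ab, T_alpha=res.T_alpha, T_beta=res.T_beta,
                       S_inf=res.S_inf)
        records.append(rec)
    return SweepResult(parameter_name=parameter_name,
                       values=np.asarray(values, dtype=float),
                       records=records, base=base)


def scaling_exponent(x_values: Sequence[float],
                     T_values: Sequence[float]) -> float:
    """Least-squares power-law exponent: slope of log T against log x."""
    x = np.asarray(x_values, dtype=float)
    T = np.asarray(T_values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a power-law fit")
    if np.any(x <= 0) or np.any(T <= 0):
        raise ValueError("power-law fit requires strictly positive data")
    slope, _ = np.polyfit(np.log(x), np.log(T), 1)
    return float(slope)


def compare_advection_modes(base: DimensionlessParameters,
                            cfg: Optional[SolverConfig] = None,
                            until: str = "end") -> dict[str, SimulationResult]:
    """Run the same configuration under the three advective-velocity choices.

    ``fluid`` is the porous-media model default (pore fluid drifts toward the
    reaction sites, accelerating corrosion), ``none`` switches advection off,
    and ``solid`` drags the dissolved species with the crystal structure
    (drift away from the reaction sites).  The final size is shared exactly:
    it follows from stoichiometry alone.
    """
    if cfg is None:
        cfg = SolverConfig()
    return {mode: simulate(base, replace(cfg, advection_mode=mode), until=until)
            for mode in ("fluid", "none", "solid")}
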