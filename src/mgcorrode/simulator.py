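"""Phase-sequenced time integration of the corrosion model.

The spatially discretised system (interior concentration nodes plus the
interface positions) is integrated per phase with a stiff variable-order BDF
solver; each phase terminates at a sign-change event (CO2 exhausted at the
joint interface, Mg core exhausted, hydroxide layer exhausted) located by the
integrator's root finding.  Transitions re-seed or re-mesh the zones:

* The initial state is singular (all interfaces coincide), so integration
  starts from a small time offset ``tau0`` with the nascent zones seeded at
  quasi-steady thin-layer profiles; results are insensitive to the seeding
  (see docs/methods.md).
* Interfaces are never driven exactly to zero: an interface reaching
  ``stop_radius`` counts as exhausted, avoiding the 1/r**d coordinate
  singularity at the origin at the cost of an O(stop_radius**(d+1)) volume
  truncation.

The outer radius S is algebraic throughout (mass conservation), never an ODE
component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .conservation import final_size, magnesium_balance_residual, outer_radius
from .discretization import assemble_phase_rhs, interface_rates
from .parameters import DimensionlessParameters
from .state import Phase, PhaseState

__all__ = [
    "SolverConfig",
    "Snapshot",
    "SimulationResult",
    "SimulationError",
    "initialize_case",
    "integrate_phase",
    "advance_phase",
    "simulate",
]

logger = logging.getLogger("mgcorrode")

# Event labels.
EVENT_CO2_EXHAUSTED = "co2_exhausted"
EVENT_MG_EXHAUSTED = "mg_exhausted"
EVENT_HYDROXIDE_EXHAUSTED = "hydroxide_exhausted"


class SimulationError(RuntimeError):
    """Integration failure, annotated with phase and time."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration.

    ``n1``/``n2`` are interior nodes per zone; ``tau0`` the start-time offset
    for the singular initial state; ``delta_seed`` the relative thickness of
    freshly seeded zones; ``stop_radius`` the interface value treated as zero
    (default ``1e-6 * S0``, resolved at run time); ``advection_mode`` one of
    ``fluid`` / ``none`` / ``solid``.
    """

    n1: int = 100
    n2: int = 100
    rtol: float = 1e-7
    atol: float = 1e-9
    tau0: float = 1e-8
    delta_seed: float = 1e-5
    stop_radius: Optional[float] = None
    advection_mode: str = "fluid"
    snapshot_times: tuple = ()
    max_time: float = 1e6
    first_step: Optional[float] = None
    upwind: bool = False  # first-order upwind advection (central by default)
    #: Relative hydroxide-layer thickness below which (in the terminal phases,
    #: alpha = 0) the zone-1 water field is held at its quasi-steady uniform
    #: limit.  Exact for the interface dynamics -- the hydroxide-exhaustion
    #: rate depends only on the CO2 gradient -- and avoids the ill-conditioned
    #: 1/width**2 diffusion operator on a vanishing zone.
    thin_zone_freeze: float = 1e-3

    def __post_init__(self) -> None:
        if self.n1 < 20 or self.n2 < 20:
            raise ValueError("n1 and n2 must be at least 20")
        if not self.tau0 > 0:
            raise ValueError("tau0 must be positive (degenerate zones are not "
                             "integrable from t = 0)")
        if not 0 < self.delta_seed < 1e-2:
            raise ValueError("delta_seed must lie in (0, 1e-2)")
        if self.advection_mode not in ("fluid", "none", "solid"):
            raise ValueError(f"unknown advection mode {self.advection_mode!r}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")

    def resolve_stop_radius(self, p: DimensionlessParameters) -> float:
        return self.stop_radius if self.stop_radius is not None else 1e-6 * p.S0


@dataclass
class Snapshot:
    """Concentration profiles at one output time (boundary nodes included)."""

    t: float
    phase: str
    r1: Optional[np.ndarray]
    W1: Optional[np.ndarray]
    r2: np.ndarray
    W2: np.ndarray
    C2: np.ndarray


@dataclass
class SimulationResult:
    """Interface trajectories, transition times and snapshots of one run."""

    params: DimensionlessParameters
    config: SolverConfig
    t: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    S: np.ndarray
    phase: np.ndarray
    T_ab: Optional[float]
    T_alpha: Optional[float]
    T_beta: Optional[float]
    S_inf: float
    snapshots: list = field(default_factory=list)

    def times(self) -> dict:
        return {"T_ab": self.T_ab, "T_alpha": self.T_alpha,
                "T_beta": self.T_beta, "S_inf": self.S_inf}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "alpha": self.alpha,
                             "beta": self.beta, "S": self.S,
                             "phase": self.phase})


# --------------------------------------------------------------------------
# packing / unpacking of the ODE state vector per phase
# --------------------------------------------------------------------------

class _PhaseSystem:
    """Maps PhaseState <-> flat ODE vector for one phase and builds the RHS."""

    def __init__(self, phase: Phase, p: DimensionlessParameters,
                 cfg: SolverConfig, n1: int, n2: int,
                 freeze_w1: bool = False):
        self.phase = phase
        self.p = p
        self.cfg = cfg
        self.freeze_w1 = freeze_w1
        # Floor applied to interface positions during trial RHS evaluations:
        # the stiff solver may probe slightly past a terminal event before the
        # event root-finding localises it.
        self._floor = 0.1 * cfg.resolve_stop_radius(p)
        self.n1 = n1 if phase.has_zone1 else 0
        self.n2 = n2
        if phase.joint_interface:
            self.idx_beta = 2 * n2
            self.idx_alpha = None
            self.size = 2 * n2 + 1
        elif phase.alpha_is_zero:
            self.idx_beta = self.n1 + 2 * n2
            self.idx_alpha = None
            self.size = self.n1 + 2 * n2 + 1
        else:
            self.idx_alpha = self.n1 + 2 * n2
            self.idx_beta = self.idx_alpha + 1
            self.size = self.n1 + 2 * n2 + 2

    def pack(self, state: PhaseState) -> np.ndarray:
        parts = []
        if self.phase.has_zone1:
            parts.append(state.W1)
        parts.extend([state.W2, state.C2])
        if self.idx_alpha is not None:
            parts.append([state.alpha])
        parts.append([state.beta])
        return np.concatenate(parts)

    def unpack(self, t: float, y: np.ndarray) -> PhaseState:
        n1, n2 = self.n1, self.n2
        off = 0
        W1 = None
        if self.phase.has_zone1:
            W1 = y[:n1]
            off = n1
        W2 = y[off:off + n2]
        C2 = y[off + n2:off + 2 * n2]
        beta = max(float(y[self.idx_beta]), self._floor)
        if self.phase.joint_interface:
            alpha = beta
        elif self.phase.alpha_is_zero:
            alpha = 0.0
        else:
            alpha = min(max(float(y[self.idx_alpha]), 0.0), beta)
        S = outer_radius(alpha, beta, self.p)
        return PhaseState(phase=self.phase, t=t, alpha=alpha, beta=beta,
                          S=S, W1=W1, W2=W2, C2=C2)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        state = self.unpack(t, y)
        dW1, dW2, dC2, ad, bd = assemble_phase_rhs(
            state, self.p, self.cfg.advection_mode,
            freeze_zone1=self.freeze_w1, upwind=self.cfg.upwind)
        out = np.empty(self.size)
        off = 0
        if dW1 is not None:
            out[:self.n1] = dW1
            off = self.n1
        out[off:off + self.n2] = dW2
        out[off + self.n2:off + 2 * self.n2] = dC2
        if self.idx_alpha is not None:
            out[self.idx_alpha] = ad
        out[self.idx_beta] = bd
        return out

    def jac_sparsity(self):
        """Conservative Jacobian sparsity: per-field tridiagonals plus dense
        coupling through the interface reconstructions and positions."""
        N = self.size
        A = lil_matrix((N, N), dtype=np.int8)
        blocks = []
        off = 0
        if self.phase.has_zone1:
            blocks.append((0, self.n1))
            off = self.n1
        blocks.append((off, self.n2))
        blocks.append((off + self.n2, self.n2))
        dense_cols = set()
        for start, n in blocks:
            for j in range(n):
                i = start + j
                A[i, i] = 1
                if j > 0:
                    A[i, i - 1] = 1
                if j < n - 1:
                    A[i, i + 1] = 1
            dense_cols.update((start, start + 1, start + n - 2, start + n - 1))
        if self.idx_alpha is not None:
            dense_cols.add(self.idx_alpha)
        dense_cols.add(self.idx_beta)
        cols = sorted(dense_cols)
        A[:, cols] = 1
        return A.tocsr()


# --------------------------------------------------------------------------
# initial and transition states
# --------------------------------------------------------------------------

def initialize_case(p: DimensionlessParameters, cfg: SolverConfig,
                    case: Optional[int] = None) -> PhaseState:
    """Seeded state at t = tau0 replacing the singular t = 0 condition.

    Case 2 starts in phase 2.1 with the joint interface displaced by its
    leading-order speed -kappa/gamma0 (ambient water at the surface) and
    uniform ambient concentrations.  Case 1 starts in phase 1.1 with both
    product zones seeded at thickness ``delta_seed * S0``, water linear across
    the hydroxide zone (0 at the Mg surface, ambient at beta) and ambient
    conditions in the carbonate zone.
    """
    if case is not None and case != p.case:
        raise ValueError(
            f"requested Case {case} but parameters define Case {p.case} "
            f"(kappa={'inf' if p.instantaneous else p.kappa})")
    n1, n2 = cfg.n1, cfg.n2
    S0 = p.S0
    if p.case == 2:
        beta = S0 - (p.kappa / p.gamma0) * cfg.tau0
        state = PhaseState(
            phase=Phase.P2_1, t=cfg.tau0, alpha=beta, beta=beta,
            S=outer_radius(beta, beta, p),
            W1=None, W2=np.ones(n2), C2=np.ones(n2))
    else:
        delta = cfg.delta_seed * S0
        alpha = S0 - 2.0 * delta
        beta = S0 - delta
        if alpha <= 0:
            raise ValueError("delta_seed too large for this S0")
        rho_int = np.linspace(0.0, 1.0, n1 + 2)[1:-1]
        state = PhaseState(
            phase=Phase.P1_1, t=cfg.tau0, alpha=alpha, beta=beta,
            S=outer_radius(alpha, beta, p),
            W1=rho_int.copy(), W2=np.ones(n2), C2=np.ones(n2))
    state.validate()
    return state


def _interp_zone(r_old: np.ndarray, vals_old: np.ndarray,
                 r_new: np.ndarray) -> np.ndarray:
    return np.interp(r_new, r_old, vals_old)


def _zone_nodes(inner: float, outer: float, n: int,
                interior_only: bool = True) -> np.ndarray:
    r = np.linspace(inner, outer, n + 2)
    return r[1:-1] if interior_only else r


def advance_phase(state: PhaseState, event: str, p: DimensionlessParameters,
                  cfg: SolverConfig) -> PhaseState:
    """Map the state at a terminal event to the starting state of the next phase."""
    phase = state.phase
    if phase is Phase.P2_1 and event == EVENT_CO2_EXHAUSTED:
        return _seed_hydroxide_zone(state, p, cfg)
    if phase in (Phase.P1_1, Phase.P2_2) and event == EVENT_MG_EXHAUSTED:
        return _collapse_alpha(state, p, cfg)
    if phase in (Phase.P1_2, Phase.P2_3) and event == EVENT_HYDROXIDE_EXHAUSTED:
        done = replace(state, phase=Phase.DONE)
        done.validate()
        return done
    raise ValueError(f"event {event!r} inconsistent with phase {phase.value}")


def _seed_hydroxide_zone(state: PhaseState, p: DimensionlessParameters,
                         cfg: SolverConfig) -> PhaseState:
    """P2_1 -> P2_2: seed a thin Mg(OH)2 zone below the joint interface."""
    rates = interface_rates(state, p, cfg.advection_mode)
    W_if = rates.boundary_values["W2_beta"]
    C_if = rates.boundary_values["C2_beta"]
    # A mild negative value is event-location undershoot; a large one simply
    # means the joint phase had zero duration (very fast surface reaction).
    if -1e-2 < C_if < -10.0 * cfg.atol:
        warnings.warn(
            f"CO2 undershoot {C_if:g} at the joint-interface transition",
            RuntimeWarning, stacklevel=2)
    delta = cfg.delta_seed * p.S0
    beta = state.beta
    alpha = beta - delta
    if alpha <= 0:
        raise SimulationError("pellet too small to seed the hydroxide zone")
    S_new = outer_radius(alpha, beta, p)
    # Re-interpolate the carbonate zone onto its (slightly) adjusted extent.
    r_old = _zone_nodes(state.beta, state.S, state.n2, interior_only=False)
    W2_old = np.concatenate(([W_if], state.W2, [1.0]))
    C2_old = np.concatenate(([max(C_if, 0.0)], state.C2, [1.0]))
    r_new = _zone_nodes(beta, S_new, cfg.n2)
    new = PhaseState(
        phase=Phase.P2_2, t=state.t, alpha=alpha, beta=beta, S=S_new,
        W1=np.full(cfg.n1, W_if),
        W2=_interp_zone(r_old, W2_old, r_new),
        C2=_interp_zone(r_old, C2_old, r_new))
    new.validate()
    return new


def _collapse_alpha(state: PhaseState, p: DimensionlessParameters,
                    cfg: SolverConfig) -> PhaseState:
    """P1_1 -> P1_2 or P2_2 -> P2_3: pin alpha at zero and re-mesh zone 1."""
    next_phase = Phase.P1_2 if state.phase is Phase.P1_1 else Phase.P2_3
    rates = interface_rates(state, p, cfg.advection_mode)
    bv = rates.boundary_values
    r1_old = _zone_nodes(state.alpha, state.beta, state.n1, interior_only=False)
    W1_old = np.concatenate(([bv["W1_alpha"]], state.W1, [bv["W_beta"]]))
    r1_new = _zone_nodes(0.0, state.beta, cfg.n1)
    S_new = outer_radius(0.0, state.beta, p)
    r2_old = _zone_nodes(state.beta, state.S, state.n2, interior_only=False)
    W2_old = np.concatenate(([bv["W_beta"]], state.W2, [1.0]))
    C2_old = np.concatenate(([0.0], state.C2, [1.0]))
    r2_new = _zone_nodes(state.beta, S_new, cfg.n2)
    new = PhaseState(
        phase=next_phase, t=state.t, alpha=0.0, beta=state.beta, S=S_new,
        W1=_interp_zone(r1_old, W1_old, r1_new),
        W2=_interp_zone(r2_old, W2_old, r2_new),
        C2=_interp_zone(r2_old, C2_old, r2_new))
    new.validate()
    return new


# --------------------------------------------------------------------------
# per-phase integration
# --------------------------------------------------------------------------

_PHASE_EVENT = {
    Phase.P2_1: EVENT_CO2_EXHAUSTED,
    Phase.P1_1: EVENT_MG_EXHAUSTED,
    Phase.P2_2: EVENT_MG_EXHAUSTED,
    Phase.P1_2: EVENT_HYDROXIDE_EXHAUSTED,
    Phase.P2_3: EVENT_HYDROXIDE_EXHAUSTED,
}


def integrate_phase(state: PhaseState, p: DimensionlessParameters,
                    cfg: SolverConfig, recorder: Optional[list] = None):
    """Advance one phase to its terminal event.

    Returns ``(state_at_event, event_label)``.  If ``recorder`` is a list, a
    segment record (phase, accepted times, interface trajectory, dense
    interpolant when snapshots are requested) is appended to it.
    """
    phase = state.phase
    if phase is Phase.DONE:
        raise ValueError("cannot integrate a completed simulation")
    stop = cfg.resolve_stop_radius(p)
    freeze_at = cfg.thin_zone_freeze * p.S0

    # The terminal phases (alpha = 0) are integrated in two legs: the full
    # system down to a thin hydroxide layer, then with the zone-1 water field
    # frozen at its quasi-steady limit down to stop_radius.
    legs: list[tuple[bool, float]] = []
    if phase.alpha_is_zero and state.beta > freeze_at > stop:
        legs = [(False, freeze_at), (True, stop)]
    elif phase.alpha_is_zero:
        legs = [(state.beta <= freeze_at, stop)]
    else:
        legs = [(False, stop)]

    end_state = state
    for freeze_w1, target in legs:
        end_state = _integrate_leg(end_state, p, cfg, freeze_w1, target,
                                   recorder)
    label = _PHASE_EVENT[phase]
    logger.info("phase %s ended (%s) at t=%.6g: alpha=%.6g beta=%.6g S=%.6g",
                phase.value, label, end_state.t, end_state.alpha,
                end_state.beta, end_state.S)
    return end_state, label


def _integrate_leg(state: PhaseState, p: DimensionlessParameters,
                   cfg: SolverConfig, freeze_w1: bool, target: float,
                   recorder: Optional[list]) -> PhaseState:
    """Integrate one leg of a phase to its terminal event and return the state."""
    phase = state.phase
    sysm = _PhaseSystem(phase, p, cfg, state.n1 or cfg.n1, state.n2,
                        freeze_w1=freeze_w1)
    if phase.joint_interface:
        def event(t, y, _sys=sysm):
            st = _sys.unpack(t, y)
            return interface_rates(
                st, p, cfg.advection_mode).boundary_values["C2_beta"]
    elif phase.alpha_is_zero:
        def event(t, y, _i=sysm.idx_beta, _tg=target):
            return y[_i] - _tg
    else:
        def event(t, y, _i=sysm.idx_alpha, _tg=target):
            return y[_i] - _tg
    event.terminal = True
    event.direction = -1

    y0 = sysm.pack(state)
    if phase.joint_interface and event(state.t, y0) <= 0.0:
        # Very fast surface reaction: CO2 is already exhausted at the joint
        # interface at the seeded start, so the joint phase has zero duration.
        logger.info("phase 2.1 has zero duration at this kappa (CO2 already "
                    "exhausted at t=%g)", state.t)
        return state
    want_dense = bool(cfg.snapshot_times)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning,
                                module="scipy.integrate")
        sol = solve_ivp(
            sysm.rhs, (state.t, state.t + cfg.max_time), y0,
            method="BDF", rtol=cfg.rtol, atol=cfg.atol,
            events=[event], jac_sparsity=sysm.jac_sparsity(),
            dense_output=want_dense, first_step=cfg.first_step)
    if sol.status == -1:
        raise SimulationError(
            f"integration failed in phase {phase.value} at t={sol.t[-1]:g}: "
            f"{sol.message}")
    if sol.status == 0:
        raise SimulationError(
            f"phase {phase.value} exceeded max_time={cfg.max_time:g} "
            f"without reaching its terminal event")

    logger.debug("phase %s leg%s: %d steps, %d rhs evals, %d jacobians",
                 phase.value, " (zone-1 frozen)" if freeze_w1 else "",
                 len(sol.t) - 1, sol.nfev, sol.njev)
    t_end = float(sol.t_events[0][0])
    y_end = sol.y_events[0][0]
    end_state = sysm.unpack(t_end, y_end)
    end_state.validate()

    if recorder is not None:
        beta_tr = sol.y[sysm.idx_beta]
        if sysm.idx_alpha is not None:
            alpha_tr = sol.y[sysm.idx_alpha]
        elif phase.joint_interface:
            alpha_tr = beta_tr.copy()
        else:
            alpha_tr = np.zeros_like(beta_tr)
        d1 = p.d + 1
        wa, wb = p.omega_alpha, p.omega_beta
        S_tr = (wa * wb * p.S0**d1 - (wb - 1.0) * beta_tr**d1
                - wb * (wa - 1.0) * alpha_tr**d1) ** (1.0 / d1)
        recorder.append({
            "phase": phase, "system": sysm,
            "t": np.append(sol.t, t_end),
            "alpha": np.append(alpha_tr, end_state.alpha),
            "beta": np.append(beta_tr, end_state.beta),
            "S": np.append(S_tr, end_state.S),
            "sol": sol.sol if want_dense else None,
        })
    return end_state


def _snapshot_from_segment(seg: dict, t: float,
                           p: DimensionlessParameters,
                           cfg: SolverConfig) -> Snapshot:
    sysm: _PhaseSystem = seg["system"]
    y = seg["sol"](t)
    st = sysm.unpack(t, y)
    rates = interface_rates(st, p, cfg.advection_mode)
    bv = rates.boundary_values
    if st.phase.joint_interface:
        r1 = W1 = None
        W2 = np.concatenate(([bv["W2_beta"]], st.W2, [1.0]))
        C2 = np.concatenate(([bv["C2_beta"]], st.C2, [1.0]))
    else:
        inner1 = 0.0 if st.phase.alpha_is_zero else st.alpha
        r1 = np.linspace(inner1, st.beta, st.n1 + 2)
        W1 = np.concatenate(([bv["W1_alpha"]], st.W1, [bv["W_beta"]]))
        W2 = np.concatenate(([bv["W_beta"]], st.W2, [1.0]))
        C2 = np.concatenate(([0.0], st.C2, [1.0]))
    r2 = np.linspace(st.beta, st.S, st.n2 + 2)
    return Snapshot(t=t, phase=st.phase.value, r1=r1, W1=W1, r2=r2, W2=W2, C2=C2)


def simulate(p: DimensionlessParameters, cfg: Optional[SolverConfig] = None,
             until: str = "end") -> SimulationResult:
    """Run the full corrosion history (or stop at an intermediate milestone).

    ``until`` is one of ``"end"`` (hydroxide exhausted), ``"T_alpha"`` (Mg
    exhausted) or ``"T_ab"`` (CO2 first exhausted at the joint interface;
    Case 2 only) — partial runs are much cheaper when only the early
    timescales are of interest.
    """
    if cfg is None:
        cfg = SolverConfig()
    if until not in ("end", "T_beta", "T_alpha", "T_ab"):
        raise ValueError(f"unknown stop milestone {until!r}")
    state = initialize_case(p, cfg)
    segments: list = []
    T_ab = T_alpha = T_beta = None

    while state.phase is not Phase.DONE:
        state, label = integrate_phase(state, p, cfg, recorder=segments)
        resid = magnesium_balance_residual(state, p)
        if resid > 1e-8 * max(1.0, p.S0) ** (p.d + 1):
            raise SimulationError(
                f"magnesium balance violated (residual {resid:g}) at t={state.t:g}")
        if label == EVENT_CO2_EXHAUSTED:
            T_ab = state.t
        elif label == EVENT_MG_EXHAUSTED:
            T_alpha = state.t
        else:
            T_beta = state.t
        if (until == "T_ab" and T_ab is not None) or \
           (until == "T_alpha" and T_alpha is not None):
            break
        state = advance_phase(state, label, p, cfg)

    t = np.concatenate([seg["t"] for seg in segments])
    alpha = np.concatenate([seg["alpha"] for seg in segments])
    beta = np.concatenate([seg["beta"] for seg in segments])
    S = np.concatenate([seg["S"] for seg in segments])
    phase_lbl = np.concatenate([
        np.full(len(seg["t"]), seg["phase"].value, dtype=object)
        for seg in segments])

    snapshots = []
    for ts in cfg.snapshot_times:
        for seg in segments:
            if seg["sol"] is not None and seg["t"][0] <= ts <= seg["t"][-1]:
                snapshots.append(_snapshot_from_segment(seg, ts, p, cfg))
                break

    return SimulationResult(
        params=p, config=cfg, t=t, alpha=alpha, beta=beta, S=S,
        phase=phase_lbl, T_ab=T_ab, T_alpha=T_alpha, T_beta=T_beta,
        S_inf=final_size(p), snapshots=snapshots)
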