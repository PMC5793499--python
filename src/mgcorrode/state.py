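"""Phase labels and the simulator state container.

Corrosion proceeds through a fixed sequence of phases distinguished by which
zones exist and which interface conditions are active:

Case 1 (instantaneous Mg-water reaction, kappa = inf):
    P1_1  both product zones present, Mg core shrinking (0 < alpha < beta)
    P1_2  Mg exhausted (alpha = 0), hydroxide layer shrinking

Case 2 (finite kappa):
    P2_1  joint interface alpha = beta: CO2 reaches the reaction site so fast
          that hydroxide converts on production; only the carbonate zone exists
    P2_2  CO2 exhausted at beta; hydroxide layer grows between alpha and beta
    P2_3  Mg exhausted (alpha = 0), hydroxide layer shrinking

``DONE`` marks complete conversion to carbonate (beta exhausted).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["Phase", "PhaseState"]


class Phase(enum.Enum):
    P1_1 = "1.1"
    P1_2 = "1.2"
    P2_1 = "2.1"
    P2_2 = "2.2"
    P2_3 = "2.3"
    DONE = "done"

    @property
    def has_zone1(self) -> bool:
        """Whether a distinct Mg(OH)2 zone (and W1 grid) exists."""
        return self in (Phase.P1_1, Phase.P1_2, Phase.P2_2, Phase.P2_3)

    @property
    def alpha_is_zero(self) -> bool:
        """Phases after Mg exhaustion: zone 1 spans (0, beta)."""
        return self in (Phase.P1_2, Phase.P2_3)

    @property
    def joint_interface(self) -> bool:
        """Phase 2.1: alpha and beta coincide."""
        return self is Phase.P2_1

    @property
    def mg_core_present(self) -> bool:
        return self in (Phase.P1_1, Phase.P2_1, Phase.P2_2)


@dataclass
class PhaseState:
    """Instantaneous simulator state.

    ``W1`` holds interior-node water concentrations on the hydroxide zone
    (absent in P2_1); ``W2`` and ``C2`` hold water and CO2 on the carbonate
    zone.  Boundary values are not stored: they are reconstructed from the
    active interface conditions.  ``S`` is always the algebraic outer radius
    implied by (alpha, beta) through magnesium conservation.
    """

    phase: Phase
    t: float
    alpha: float
    beta: float
    S: float
    W1: Optional[np.ndarray]
    W2: np.ndarray
    C2: np.ndarray

    def __post_init__(self) -> None:
        # Only structural checks here: trial steps of the stiff integrator may
        # transiently violate the ordering invariants, so those live in
        # validate() and are asserted at accepted states.
        if self.phase.joint_interface and self.W1 is not None:
            raise ValueError("zone 1 grid must be absent in phase 2.1")
        if self.phase.has_zone1 and self.W1 is None:
            raise ValueError(f"zone 1 grid required in phase {self.phase.value}")

    def validate(self) -> None:
        """Check interface ordering; raise ValueError if inconsistent."""
        if not (0.0 <= self.alpha <= self.beta <= self.S):
            raise ValueError(
                f"interfaces must satisfy 0 <= alpha <= beta <= S, got "
                f"alpha={self.alpha}, beta={self.beta}, S={self.S}")

    @property
    def n1(self) -> int:
        return 0 if self.W1 is None else len(self.W1)

    @property
    def n2(self) -> int:
        return len(self.W2)

    # --- checkpoint serialisation -------------------------------------------
    def to_json(self) -> str:
        payload = {
            "phase": self.phase.value,
            "t": self.t,
            "alpha": self.alpha,
            "beta": self.beta,
            "S": self.S,
            "W1": None if self.W1 is None else self.W1.tolist(),
            "W2": self.W2.tolist(),
            "C2": self.C2.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PhaseState":
        payload = json.loads(text)
        return cls(
            phase=Phase(payload["phase"]),
            t=float(payload["t"]),
            alpha=float(payload["alpha"]),
            beta=float(payload["beta"]),
            S=float(payload["S"]),
            W1=None if payload["W1"] is None else np.asarray(payload["W1"], float),
            W2=np.asarray(payload["W2"], float),
            C2=np.asarray(payload["C2"], float),
        )
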