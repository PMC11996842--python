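"""Two-dimensional interference model of the conjunction fallacy.

The Linda problem: participants judge "Linda is a bank teller and a
feminist" (T∧F) more probable than "Linda is a bank teller" (T), which is
impossible classically.  The quantum-probability account represents the
belief state as a unit vector in the plane spanned by |B⟩ (bank teller) and
|F⟩ (feminist),

    |ψ⟩ = cosθ|B⟩ + sinθ|F⟩,

and the conjunction as a second basis direction

    |B_F⟩ = cosφ|B⟩ + sinφ|F⟩.

Projective measurement gives P(T) = cos²θ and P(T∧F) = cos²(θ−φ), so the
fallacy P(T∧F) > P(T) occurs exactly when |θ−φ| < θ: constructive
interference between the bank-teller and feminist components.

All angles are radians internally; use :meth:`AngleModel.from_degrees` at
the API boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .hilbert import StateVector, make_state

__all__ = [
    "AngleModel",
    "belief_state",
    "conjunction_basis_state",
    "p_single",
    "p_conjunction",
    "fallacy_holds",
    "EMPIRICAL_P_SINGLE",
    "EMPIRICAL_P_CONJUNCTION",
]

#: Reference empirical anchors from the behavioural literature (typical
#: observed judgment frequencies for the Linda task). Shipped for calibration
#: demos only — they are cited values, not model outputs.
EMPIRICAL_P_SINGLE = 0.15
EMPIRICAL_P_CONJUNCTION = 0.85

_CANONICAL = (0.0, math.pi / 2)


@dataclass(frozen=True)
class AngleModel:
    """Angle parameters (radians) of the 2-D conjunction model.

    ``theta`` weights bank-teller vs feminist in the belief state; ``phi``
    fixes the direction of the conjunction basis state.  Values outside the
    canonical range [0, π/2] are accepted but flagged with a warning.
    """

    theta: float
    phi: float

    def __post_init__(self):
        for name, val in (("theta", self.theta), ("phi", self.phi)):
            if not math.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val}")
            if not (_CANONICAL[0] <= val <= _CANONICAL[1]):
                warnings.warn(
                    f"{name}={val:.4f} rad is outside the canonical range "
                    f"[0, π/2]; probabilities remain valid but the scenario "
                    f"is non-standard",
                    stacklevel=3,
                )

    @classmethod
    def from_degrees(cls, theta_deg: float, phi_deg: float) -> "AngleModel":
        return cls(math.radians(theta_deg), math.radians(phi_deg))


def belief_state(model: AngleModel) -> StateVector:
    """|ψ⟩ = cosθ|B⟩ + sinθ|F⟩ over the labelled basis {B, F}."""
    return make_state(["B", "F"], [math.cos(model.theta), math.sin(model.theta)])


def conjunction_basis_state(model: AngleModel) -> StateVector:
    """|B_F⟩ = cosφ|B⟩ + sinφ|F⟩, the conjunction direction."""
    return make_state(["B", "F"], [math.cos(model.phi), math.sin(model.phi)])


def p_single(model: AngleModel) -> float:
    """P(T) = cos²θ, the single-event (bank teller) probability."""
    return math.cos(model.theta) ** 2


def p_conjunction(model: AngleModel) -> float:
    """P(T∧F) = cos²(θ−φ), the conjunction probability."""
    return math.cos(model.theta - model.phi) ** 2


def fallacy_holds(model: AngleModel) -> bool:
    """True iff the model predicts the conjunction fallacy P(T∧F) > P(T).

    Equivalent to the angular condition |θ−φ| < θ on the canonical range;
    implemented as the direct probability comparison so it remains correct
    for any angles.
    """
    if not (0.0 < model.theta < math.pi / 2):
        warnings.warn(
            f"theta={model.theta:.4f} rad outside (0, π/2); the angular "
            f"criterion |θ−φ| < θ is only guaranteed there",
            stacklevel=2,
        )
    return p_conjunction(model) > p_single(model)
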