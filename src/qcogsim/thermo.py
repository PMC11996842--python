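"""Observer-thermodynamics closed forms.

Small calculators for the information-energetic side of the observer
picture: the Landauer bound on one-bit erasure, the energy of a one-bit
"question" posed to a qubit, Schwarzschild/Bekenstein–Hawking quantities
(entropy as the information capacity of a boundary), and the
fitness-beats-truth probability from evolutionary perception games.

SI units throughout.  Constants default to CODATA values and are injectable
(e.g. k_B = 1) for unit-free property tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "CODATA",
    "landauer_min_energy",
    "question_energy",
    "black_hole_quantities",
    "fbt_probability",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (SI). Override for toy-unit tests."""

    k_B: float = 1.380649e-23      # J/K
    hbar: float = 1.054571817e-34  # J·s
    G: float = 6.67430e-11         # m³ kg⁻¹ s⁻²
    c: float = 299792458.0         # m/s

    def __post_init__(self):
        for name in ("k_B", "hbar", "G", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


CODATA = PhysicalConstants()


def landauer_min_energy(T: float, constants: PhysicalConstants = CODATA) -> float:
    """Minimum free energy ln(2)·k_B·T to record or erase one bit at T (K)."""
    if T <= 0:
        raise ValueError("temperature must be > 0 K")
    return math.log(2.0) * constants.k_B * T


def question_energy(
    beta: float, T: float, constants: PhysicalConstants = CODATA
) -> float:
    """Energy β·k_B·T of a one-bit question at inefficiency factor β.

    β = ln 2 is the Landauer limit; β ≥ ln 2 allows for practical
    inefficiencies (a warning is emitted below the limit).
    """
    if T <= 0:
        raise ValueError("temperature must be > 0 K")
    if beta < math.log(2.0):
        warnings.warn(
            f"beta={beta} is below the Landauer limit ln 2 ≈ 0.693; no "
            f"physical one-bit operation can be this cheap",
            stacklevel=2,
        )
    return beta * constants.k_B * T


def black_hole_quantities(
    M: float, constants: PhysicalConstants = CODATA
) -> dict[str, float]:
    """Schwarzschild radius, horizon area and Bekenstein–Hawking entropy.

    R_s = 2GM/c²,  A = 4πR_s² = 16πG²M²/c⁴,  S = 4πk_B G M²/(ħc).

    The entropy is recomputed through the area route S = k_B c³ A/(4Għ)
    and the two must agree to 1e−10 relative — a dimensional consistency
    check wired into the function itself.
    """
    if M <= 0:
        raise ValueError("mass must be > 0 kg")
    k_B, hbar, G, c = constants.k_B, constants.hbar, constants.G, constants.c
    radius = 2.0 * G * M / c**2
    area = 16.0 * math.pi * G**2 * M**2 / c**4
    entropy_mass = 4.0 * math.pi * k_B * G * M**2 / (hbar * c)
    entropy_area = k_B * c**3 * area / (4.0 * G * hbar)
    if abs(entropy_area - entropy_mass) > 1e-10 * abs(entropy_mass):
        raise ArithmeticError(
            "area-route and mass-route entropies disagree beyond 1e-10 "
            "relative; check the injected constants"
        )
    return {"radius": radius, "area": area, "entropy": entropy_mass}


def fbt_probability(n_states: int) -> float:
    """Fitness-beats-truth probability (|X|−3)/(|X|−1).

    The probability that a fitness-tuned perceptual strategy drives a
    veridical ("truth") strategy to extinction, as a function of the number
    of distinguishable perceptual states |X|.  Strictly increasing in
    |X| and → 1 as |X| → ∞: richer perceptual spaces favor interface-style
    perception ever more strongly.  Defined for n_states ≥ 3 (zero at the
    n = 3 boundary).
    """
    n = int(n_states)
    if n < 3:
        raise ValueError("fbt_probability requires n_states >= 3")
    return (n - 3) / (n - 1)
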