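"""Observer-coupled perturbation layer.

Two mechanisms by which an observer's directed attention modifies standard
quantum(-cognitive) probabilities:

1. A multiplicative *conscious-influence factor*

       g = 1 + η · |⟨ψ_focus|ψ_init⟩|²

   scaling the Born probability of the focused outcome, where η ≥ 0 is a
   small influence strength and the overlap measures the alignment between
   the observer's initial internal state and their focused intent.  η = 0
   recovers standard quantum mechanics exactly.

2. Small contextual shifts (δθ, δφ) of the conjunction-model angles,
   handled exactly (cos² of the shifted angle difference) and to first
   order in the shifts.

The module also implements first-order time-dependent perturbation theory
for a weak interaction H_int = λ(Â_sys ⊗ Â_intO) between a system and an
observer space, under the simplifying assumption that the observer state is
static (H_intO = 0).  Units: ħ = 1, so couplings and frequencies are inverse
times.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .conjunction import AngleModel, p_conjunction
from .hilbert import ContractError, LinearOperator, StateVector, make_state

__all__ = [
    "ObserverContext",
    "PerturbationParams",
    "conscious_influence_factor",
    "modified_probability",
    "renormalized_distribution",
    "first_order_conjunction_shift",
    "exact_perturbed_conjunction",
    "combined_probability",
    "combined_probability_expansion",
    "zeroth_order_amplitude",
    "first_order_amplitude_correction",
    "corrected_probability",
]

#: above this η the "small influence" reading is dubious
_ETA_WARN = 0.2
#: above this |δ| (radians) first-order truncation is dubious
_DELTA_WARN = 0.2


@dataclass(frozen=True)
class ObserverContext:
    """Observer focus/initial states plus influence and coupling strengths.

    ``focus_state`` and ``initial_state`` live on the same observer-space
    basis and must be normalized.  ``eta`` is the dimensionless influence
    strength; ``lam`` the interaction coupling λ (inverse-time units, ħ=1).
    """

    focus_state: StateVector
    initial_state: StateVector
    eta: float = 0.0
    lam: float = 0.0

    def __post_init__(self):
        if tuple(self.focus_state.labels) != tuple(self.initial_state.labels):
            raise ContractError("focus and initial states must share a basis")
        for name, st in (("focus", self.focus_state), ("initial", self.initial_state)):
            if not st.is_normalized():
                raise ContractError(f"{name} state must be normalized")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.eta > _ETA_WARN:
            warnings.warn(
                f"eta={self.eta} exceeds {_ETA_WARN}; the perturbative "
                f"reading of the influence factor is questionable",
                stacklevel=3,
            )

    @classmethod
    def from_overlap(
        cls, eta: float, overlap_sq: float, lam: float = 0.0
    ) -> "ObserverContext":
        """Build a minimal 2-D observer context with a given squared overlap.

        Convenience for scenarios that specify only |⟨focus|init⟩|² rather
        than explicit observer states.
        """
        if not (0.0 <= overlap_sq <= 1.0):
            raise ValueError("overlap_sq must be in [0, 1]")
        focus = make_state(["f", "f_perp"], [1.0, 0.0])
        init = make_state(
            ["f", "f_perp"],
            [math.sqrt(overlap_sq), math.sqrt(1.0 - overlap_sq)],
        )
        return cls(focus_state=focus, initial_state=init, eta=eta, lam=lam)

    @property
    def overlap(self) -> complex:
        """⟨ψ_focus|ψ_init⟩."""
        return self.focus_state.inner(self.initial_state)

    @property
    def overlap_sq(self) -> float:
        return abs(self.overlap) ** 2


@dataclass(frozen=True)
class PerturbationParams:
    """Small contextual angle shifts δθ, δφ in radians."""

    delta_theta: float
    delta_phi: float

    def __post_init__(self):
        for name, val in (
            ("delta_theta", self.delta_theta),
            ("delta_phi", self.delta_phi),
        ):
            if abs(val) > _DELTA_WARN:
                warnings.warn(
                    f"|{name}|={abs(val):.3f} rad exceeds {_DELTA_WARN}; "
                    f"first-order formulas may be inaccurate",
                    stacklevel=3,
                )

    @classmethod
    def from_degrees(cls, delta_theta_deg: float, delta_phi_deg: float):
        return cls(math.radians(delta_theta_deg), math.radians(delta_phi_deg))


def conscious_influence_factor(ctx: ObserverContext) -> float:
    """g = 1 + η·|⟨ψ_focus|ψ_init⟩|², in [1, 1+η]."""
    return 1.0 + ctx.eta * ctx.overlap_sq


def modified_probability(p_standard: float, ctx: ObserverContext) -> float:
    """Raw observer-modified probability p·g.

    The product is reported un-renormalized (matching the closed-form
    worked examples); if it exceeds 1 it is clipped with a warning.  For a
    properly normalized distribution over a full outcome set use
    :func:`renormalized_distribution`.
    """
    if not (0.0 <= p_standard <= 1.0):
        raise ValueError("p_standard must be a probability in [0, 1]")
    p = p_standard * conscious_influence_factor(ctx)
    if p > 1.0:
        warnings.warn(
            f"modified probability {p:.6f} > 1 clipped to 1; consider the "
            f"renormalized distribution instead",
            stacklevel=2,
        )
        return 1.0
    return p


def renormalized_distribution(
    p_standard: list[float] | np.ndarray,
    factors: list[float] | np.ndarray,
) -> np.ndarray:
    """Normalized distribution pᵢgᵢ / Σⱼ pⱼgⱼ over a complete outcome set."""
    p = np.asarray(p_standard, dtype=float)
    g = np.asarray(factors, dtype=float)
    if p.shape != g.shape:
        raise ValueError("p_standard and factors must have equal length")
    w = p * g
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    return w / total


def first_order_conjunction_shift(
    model: AngleModel, pert: PerturbationParams
) -> float:
    """First-order perturbed conjunction probability.

    With Δ = θ−φ, returns  cos²Δ − sin(2Δ)·(δθ−δφ),  the linearization of
    cos²(Δ + δθ − δφ) in the angle shifts (radians).
    """
    delta = model.theta - model.phi
    return p_conjunction(model) - math.sin(2.0 * delta) * (
        pert.delta_theta - pert.delta_phi
    )


def exact_perturbed_conjunction(
    model: AngleModel, pert: PerturbationParams
) -> float:
    """Exact perturbed conjunction probability cos²(θ+δθ − (φ+δφ)).

    Serves as the exact oracle against which the first-order formula is a
    truncation.
    """
    dprime = (model.theta + pert.delta_theta) - (model.phi + pert.delta_phi)
    return math.cos(dprime) ** 2


def combined_probability(
    model: AngleModel, pert: PerturbationParams, ctx: ObserverContext
) -> float:
    """Product form: [cos²Δ − sin(2Δ)(δθ−δφ)] · g."""
    return first_order_conjunction_shift(model, pert) * conscious_influence_factor(ctx)


def combined_probability_expansion(
    model: AngleModel, pert: PerturbationParams, ctx: ObserverContext
) -> float:
    """First-order expansion dropping the O(η·δ) cross-terms.

    P ≈ P_std + P_std·η·|⟨focus|init⟩|² − sin(2Δ)(δθ−δφ).
    """
    p_std = p_conjunction(model)
    delta = model.theta - model.phi
    return (
        p_std
        + p_std * ctx.eta * ctx.overlap_sq
        - math.sin(2.0 * delta) * (pert.delta_theta - pert.delta_phi)
    )


def _check_hermitian_system(sys_H: LinearOperator) -> None:
    if not sys_H.is_hermitian():
        raise ContractError(
            "system Hamiltonian must be Hermitian here; non-Hermitian "
            "generators belong to the collapse engine"
        )


def zeroth_order_amplitude(
    sys_H: LinearOperator, psi_sys0: StateVector, target: StateVector, t: float
) -> complex:
    """A⁽⁰⁾ = ⟨target|e^{−iHt}|ψ₀⟩ under the unperturbed Hermitian dynamics."""
    _check_hermitian_system(sys_H)
    evals, evecs = np.linalg.eigh(sys_H.matrix)
    phases = np.exp(-1j * evals * t)
    U = evecs @ np.diag(phases) @ evecs.conj().T
    return complex(target.amplitudes.conj() @ U @ psi_sys0.amplitudes)


def first_order_amplitude_correction(
    sys_H: LinearOperator,
    A_sys: LinearOperator,
    psi_sys0: StateVector,
    target: StateVector,
    ctx: ObserverContext,
    t: float,
    *,
    abs_tol: float = 1e-10,
) -> complex:
    """First-order amplitude correction from the observer interaction.

    A⁽¹⁾(a, t) = −iλ ⟨ψ_focus|ψ_init⟩ ∫₀ᵗ ⟨a| Â_sys(t′) |ψ₀⟩ dt′

    where Â_sys(t′) = e^{iHt′} Â_sys e^{−iHt′} is the interaction-picture
    operator and the observer's own Hamiltonian is taken to be zero (the
    conscious state is static over the measurement).  The time integral is
    evaluated by adaptive quadrature with absolute tolerance ``abs_tol``.

    λ = 0 or an orthogonal focus/initial pair give exactly 0.
    """
    _check_hermitian_system(sys_H)
    if t < 0:
        raise ValueError("t must be >= 0")
    prefactor = -1j * ctx.lam * ctx.overlap
    if prefactor == 0 or t == 0:
        return 0.0 + 0.0j

    evals, evecs = np.linalg.eigh(sys_H.matrix)
    a_t = evecs.conj().T @ target.amplitudes   # target in the eigenbasis
    p_0 = evecs.conj().T @ psi_sys0.amplitudes
    A_eig = evecs.conj().T @ A_sys.matrix @ evecs

    def matrix_element(tp: float) -> complex:
        phases = np.exp(1j * evals * tp)
        # ⟨a|e^{iHt'} A e^{-iHt'}|ψ0⟩ in the eigenbasis
        return complex(
            (a_t.conj() * phases) @ A_eig @ (p_0 * phases.conj())
        )

    re, _ = quad(lambda tp: matrix_element(tp).real, 0.0, t, epsabs=abs_tol, limit=200)
    im, _ = quad(lambda tp: matrix_element(tp).imag, 0.0, t, epsabs=abs_tol, limit=200)
    return prefactor * complex(re, im)


def corrected_probability(a0: complex, a1: complex) -> float:
    """Probability to first order: |A⁽⁰⁾|² + 2Re(A⁽⁰⁾* A⁽¹⁾)."""
    return float(abs(a0) ** 2 + 2.0 * (np.conj(a0) * a1).real)
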