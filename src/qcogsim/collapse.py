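"""Non-Hermitian collapse engine.

Collapse toward preferred cognitive states is modelled by adding an
anti-Hermitian part −iΓ̂ to the system Hamiltonian, with Γ̂ Hermitian and
positive semidefinite.  Under

    iħ d|Ψ⟩/dt = Ĥ_total |Ψ⟩,   Ĥ_total = (Ĥ_sys − iΓ̂)⊗Î + Î⊗Ĥ_intO + Ĥ_int,

the norm of the state decays monotonically: amplitudes of states penalized
by Γ̂ are damped exponentially, which "freezes" the system into the
surviving state in the manner of the quantum Zeno effect (continuous
measurement suppressing transitions).

For the decision scenarios the dynamics are diagonal in the cognitive basis
with per-state couplings λᵢ (cognitive salience, the alignment of each state
with the observer's intent) and decay rates γᵢ ≥ 0 (free-energy penalties:
the least congruent state decays fastest).  Each amplitude then follows the
closed form

    aᵢ(t) = aᵢ(0) · e^{(−iλᵢ − γᵢ) t / ħ},

and conjunction states |x∧y⟩ = (|x⟩+|y⟩)/√2 pick up interference through
a₂(t) = (a₁(t)+a₃(t))/√2.  Raw probabilities reproduce this algebra exactly
(including the printed subtraction P(BT) = |a₃|² − P(F∧BT), which can go
negative); reported probabilities clamp negatives to zero and renormalize.

ħ = 1 throughout; λ and γ are in inverse-time units.  Dimensions are tiny
(≤ 12), so general evolution uses a dense matrix exponential per time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .hilbert import (
    STRUCTURAL_TOL,
    ContractError,
    LinearOperator,
    StateVector,
    tensor,
)

__all__ = [
    "NonHermitianSystem",
    "EvolutionResult",
    "build_total_hamiltonian",
    "build_targeted_collapse_operator",
    "analytic_amplitudes",
    "evolve",
    "conjunction_amplitude",
    "probabilities_with_interference",
    "interference_cross_term",
    "zeno_suppression_ratio",
]


@dataclass(frozen=True)
class NonHermitianSystem:
    """A diagonal non-Hermitian system over a labelled cognitive basis.

    Fields
    ------
    labels : ordered basis names, e.g. ``("F", "F∧BT", "BT")``
    lam    : per-state couplings λᵢ (real; cognitive salience)
    gamma  : per-state decay rates γᵢ ≥ 0
    a0     : initial complex amplitudes, Σ|a0ᵢ|² = 1
    hbar   : fixed at 1
    """

    labels: tuple[str, ...]
    lam: np.ndarray = field(repr=False)
    gamma: np.ndarray = field(repr=False)
    a0: np.ndarray = field(repr=False)
    hbar: float = 1.0

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        lam = np.asarray(self.lam, dtype=float).reshape(-1)
        gamma = np.asarray(self.gamma, dtype=float).reshape(-1)
        a0 = np.asarray(self.a0, dtype=complex).reshape(-1)
        n = len(labels)
        if not (len(lam) == len(gamma) == len(a0) == n):
            raise ValueError("labels, lam, gamma and a0 must have equal length")
        if (gamma < 0).any():
            raise ValueError("all decay rates gamma must be >= 0")
        if abs(np.sum(np.abs(a0) ** 2) - 1.0) > STRUCTURAL_TOL:
            raise ValueError("initial amplitudes must satisfy Σ|a0|² = 1")
        if self.hbar != 1.0:
            raise ValueError("hbar is fixed at 1 in this package")
        for arr in (lam, gamma, a0):
            arr.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "a0", a0)

    @property
    def dim(self) -> int:
        return len(self.labels)

    def generator(self) -> LinearOperator:
        """The diagonal non-Hermitian generator diag(λᵢ − iγᵢ)."""
        return LinearOperator(self.labels, np.diag(self.lam - 1j * self.gamma))


@dataclass(frozen=True)
class EvolutionResult:
    """Time-resolved amplitudes and probabilities.

    ``raw_probabilities`` follow the model algebra exactly and may exceed 1
    or go negative where interference subtractions apply;
    ``reported_probabilities`` clamp to [0, 1] and renormalize to sum to 1
    at each time.  ``norm`` is Σ|aᵢ(t)|².
    """

    labels: tuple[str, ...]
    times: np.ndarray
    amplitudes: np.ndarray          # shape (n_times, n_states)
    raw_probabilities: np.ndarray   # shape (n_times, n_states)
    norm: np.ndarray                # shape (n_times,)
    reported_probabilities: np.ndarray  # shape (n_times, n_states)

    def at(self, index: int) -> dict[str, float]:
        """Reported distribution at a time index, as a label→prob mapping."""
        return dict(zip(self.labels, self.reported_probabilities[index]))


def _clamp_renormalize(raw: np.ndarray) -> np.ndarray:
    clamped = np.clip(raw, 0.0, None)
    totals = clamped.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    out = clamped / safe
    # a fully-decayed row is reported as the uniform distribution
    flat = np.full(raw.shape[1], 1.0 / raw.shape[1])
    return np.where(totals > 0, out, flat)


def build_total_hamiltonian(
    H_sys: LinearOperator,
    Gamma: LinearOperator,
    H_intO: LinearOperator,
    H_int: LinearOperator,
) -> LinearOperator:
    """Ĥ_total = (Ĥ_sys − iΓ̂)⊗Î_intO + Î_sys⊗Ĥ_intO + Ĥ_int.

    ``H_sys`` and ``H_intO`` must be Hermitian and Γ̂ Hermitian positive
    semidefinite, so the anti-Hermitian part of the result is exactly
    −i(Γ̂⊗Î).  ``H_int`` lives on the tensor-product basis.
    """
    if not H_sys.is_hermitian():
        raise ContractError("H_sys must be Hermitian")
    if not H_intO.is_hermitian():
        raise ContractError("H_intO must be Hermitian")
    if not Gamma.is_positive_semidefinite():
        raise ContractError("Gamma must be Hermitian positive semidefinite")
    if tuple(Gamma.labels) != tuple(H_sys.labels):
        raise ContractError("Gamma must act on the system basis")

    I_sys = LinearOperator.identity(H_sys.labels)
    I_obs = LinearOperator.identity(H_intO.labels)
    effective_sys = H_sys - (1j * Gamma)
    total = tensor(effective_sys, I_obs) + tensor(I_sys, H_intO)
    if tuple(H_int.labels) != tuple(total.labels):
        raise ContractError(
            "H_int must live on the tensor-product basis "
            f"{tuple(total.labels)}"
        )
    return total + H_int


def build_targeted_collapse_operator(
    dim: int,
    target_index: int,
    gamma: float,
    labels: Sequence[str] | None = None,
) -> LinearOperator:
    """Γ̂ = γ Σ_{k≠k₀} |a_k⟩⟨a_k|: decay on every state except the target.

    Evolving under −iΓ̂ alone damps all non-target amplitudes at rate γ, so
    the reported probability of the target state tends to 1 as t → ∞
    (collapse toward |a_{k₀}⟩).
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if not (0 <= target_index < dim):
        raise IndexError(f"target_index {target_index} out of range for dim {dim}")
    if labels is None:
        labels = tuple(f"a{k}" for k in range(dim))
    diag = np.full(dim, float(gamma))
    diag[target_index] = 0.0
    return LinearOperator(tuple(labels), np.diag(diag))


def analytic_amplitudes(sys: NonHermitianSystem, times: Sequence[float]) -> EvolutionResult:
    """Closed-form diagonal evolution aᵢ(t) = aᵢ(0)e^{(−iλᵢ−γᵢ)t}.

    Valid when the system is diagonal in its own basis (the decision-task
    construction); magnitudes obey |aᵢ(t)| = |aᵢ(0)|e^{−γᵢt}.
    """
    t = np.asarray(times, dtype=float).reshape(-1)
    # (n_times, n_states)
    amps = sys.a0[None, :] * np.exp(
        (-1j * sys.lam[None, :] - sys.gamma[None, :]) * t[:, None]
    )
    raw = np.abs(amps) ** 2
    norm = raw.sum(axis=1)
    return EvolutionResult(
        labels=sys.labels,
        times=t,
        amplitudes=amps,
        raw_probabilities=raw,
        norm=norm,
        reported_probabilities=_clamp_renormalize(raw),
    )


def evolve(
    H_total: LinearOperator, psi0: StateVector, times: Sequence[float]
) -> EvolutionResult:
    """General evolution |ψ(t)⟩ = e^{−iĤt}|ψ₀⟩ for any square generator.

    A Hermitian Ĥ conserves the norm; an anti-Hermitian part −iΓ̂ with Γ̂
    PSD makes the norm non-increasing.  The matrix exponential is computed
    per time point (no Trotterization — dimensions here are tiny).
    """
    if tuple(H_total.labels) != tuple(psi0.labels):
        raise ContractError("H_total and psi0 must share a basis")
    if not psi0.is_normalized():
        raise ContractError("psi0 must be normalized")
    t = np.asarray(times, dtype=float).reshape(-1)
    amps = np.empty((len(t), psi0.dim), dtype=complex)
    for k, tk in enumerate(t):
        amps[k] = expm(-1j * H_total.matrix * tk) @ psi0.amplitudes
    raw = np.abs(amps) ** 2
    return EvolutionResult(
        labels=psi0.labels,
        times=t,
        amplitudes=amps,
        raw_probabilities=raw,
        norm=raw.sum(axis=1),
        reported_probabilities=_clamp_renormalize(raw),
    )


def conjunction_amplitude(a1: complex, a3: complex) -> complex:
    """Amplitude of the conjunction state |x∧y⟩ = (|x⟩+|y⟩)/√2:

    a₂ = (a₁ + a₃)/√2, so |a₂|² = ½(|a₁|² + |a₃|² + 2Re(a₁a₃*)) carries the
    interference cross term.
    """
    return (complex(a1) + complex(a3)) / np.sqrt(2.0)


def interference_cross_term(sys: NonHermitianSystem, t: float) -> float:
    """The cross term 2Re(a₁(0)a₃*(0) e^{(−iΔλ−Δγ_sum)t}) of |a₂(t)|².

    Δλ = λ₁−λ₃ is the salience difference and the real decay is at the sum
    γ₁+γ₃ of the two component rates.
    """
    d_lam = sys.lam[0] - sys.lam[2]
    g_sum = sys.gamma[0] + sys.gamma[2]
    z = sys.a0[0] * np.conj(sys.a0[2]) * np.exp((-1j * d_lam - g_sum) * t)
    return float(2.0 * z.real)


def probabilities_with_interference(
    sys: NonHermitianSystem, times: Sequence[float]
) -> EvolutionResult:
    """Three-state decision probabilities with the conjunction interference.

    For a basis ordered (X, X∧Y, Y) — e.g. (F, F∧BT, BT) — the component
    amplitudes a₁, a₃ follow the diagonal closed form, the conjunction
    amplitude is a₂ = (a₁+a₃)/√2, and the raw probabilities are

        P(X)    = |a₁(t)|²
        P(X∧Y)  = |a₂(t)|²
        P(Y)    = |a₃(t)|² − P(X∧Y)   (the conjunction absorbs part of Y)

    exactly as the model's algebra prescribes; P(Y) may be negative, which
    the reported distribution clamps to 0 before renormalizing.
    """
    if sys.dim != 3:
        raise ValueError("interference probabilities require a 3-state system")
    t = np.asarray(times, dtype=float).reshape(-1)
    base = analytic_amplitudes(sys, t)
    amps = np.array(base.amplitudes, copy=True)
    amps[:, 1] = (amps[:, 0] + amps[:, 2]) / np.sqrt(2.0)

    raw = np.empty_like(np.abs(amps))
    raw[:, 0] = np.abs(amps[:, 0]) ** 2
    raw[:, 1] = np.abs(amps[:, 1]) ** 2
    raw[:, 2] = np.abs(amps[:, 2]) ** 2 - raw[:, 1]
    norm = (np.abs(amps) ** 2).sum(axis=1)
    return EvolutionResult(
        labels=sys.labels,
        times=t,
        amplitudes=amps,
        raw_probabilities=raw,
        norm=norm,
        reported_probabilities=_clamp_renormalize(raw),
    )


def zeno_suppression_ratio(sys: NonHermitianSystem, t: float) -> float:
    """Suppression of non-target probability under targeted collapse.

    The target is the state of minimal decay rate (the state the collapse
    operator spares).  Returns the ratio of the reported non-target
    probability mass at time ``t`` to its initial value:  1 at γ = 0 (or
    t = 0), strictly decreasing in the decay rates, → 0 as γt → ∞ —
    continuous measurement freezing the system into the target state.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    target = int(np.argmin(sys.gamma))
    res = analytic_amplitudes(sys, [0.0, t])
    nontarget0 = 1.0 - res.reported_probabilities[0, target]
    nontarget_t = 1.0 - res.reported_probabilities[1, target]
    if nontarget0 <= 0:
        return 1.0  # already collapsed at t=0; nothing to suppress
    return float(nontarget_t / nontarget0)
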