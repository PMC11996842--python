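"""Contextual probability machinery: CPTP context maps, contextual Born
rule, and Kraus-instrument Bayesian updating.

On this reading "collapse" is an agent's Bayesian update of personal
probability assignments rather than a physical process: a measurement
scenario is a quantum instrument {Mᵢ}, outcome probabilities are
P(aᵢ) = Tr(ρMᵢ†Mᵢ), and the post-outcome state is MᵢρMᵢ†/P(aᵢ).  A
*context* — experimental conditions plus the observer's internal state —
acts on the agent's density operator through a CPTP channel before the
Born rule is applied; the identity context recovers the standard Born rule
exactly (context reduction).

The non-Hermitian decay dynamics of :mod:`qcogsim.collapse` can be absorbed
into such an instrument (see :func:`collapse_instrument`), making the two
descriptions of collapse interchangeable on shared inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .hilbert import (
    PROBABILITY_TOL,
    STRUCTURAL_TOL,
    ContractError,
    DensityOperator,
    LinearOperator,
)

__all__ = [
    "KrausInstrument",
    "ContextMap",
    "apply_context",
    "contextual_probability",
    "instrument_update",
    "qbist_mixture_update",
    "contextual_observable",
    "collapse_instrument",
]


@dataclass(frozen=True)
class KrausInstrument:
    """A quantum instrument: one or more Kraus operators per outcome.

    ``operators[i]`` is the list of Kraus operators {R_{i,k}} realizing
    outcome ``outcome_labels[i]`` via ℰᵢ(ρ) = Σₖ R_{i,k} ρ R_{i,k}†.
    Completeness Σ R†R = I is enforced within ``PROBABILITY_TOL`` unless
    ``subnormalized=True`` (an instrument covering only a sub-event).
    """

    operators: tuple[tuple[LinearOperator, ...], ...]
    outcome_labels: tuple[str, ...]
    subnormalized: bool = False

    def __post_init__(self):
        ops = tuple(tuple(group) for group in self.operators)
        if len(ops) == 0 or any(len(g) == 0 for g in ops):
            raise ValueError("each outcome needs at least one Kraus operator")
        if len(ops) != len(self.outcome_labels):
            raise ValueError("one outcome label per operator group")
        basis = tuple(ops[0][0].labels)
        for group in ops:
            for K in group:
                if tuple(K.labels) != basis:
                    raise ContractError("all Kraus operators must share a basis")
        object.__setattr__(self, "operators", ops)
        object.__setattr__(self, "outcome_labels", tuple(self.outcome_labels))
        if not self.subnormalized and not self.is_complete():
            raise ContractError(
                "Kraus operators do not satisfy Σ K†K = I; "
                "pass subnormalized=True for a sub-event instrument"
            )

    @property
    def basis(self) -> tuple[str, ...]:
        return tuple(self.operators[0][0].labels)

    @property
    def dim(self) -> int:
        return self.operators[0][0].dim

    def completeness_sum(self) -> np.ndarray:
        total = np.zeros((self.dim, self.dim), dtype=complex)
        for group in self.operators:
            for K in group:
                total += K.matrix.conj().T @ K.matrix
        return total

    def is_complete(self, tol: float = PROBABILITY_TOL) -> bool:
        return bool(
            np.allclose(self.completeness_sum(), np.eye(self.dim), atol=tol, rtol=0)
        )

    def as_channel_matrices(self) -> list[np.ndarray]:
        return [K.matrix for group in self.operators for K in group]


@dataclass(frozen=True)
class ContextMap:
    """A context C′ acting as a single CPTP channel on density operators."""

    kraus: KrausInstrument
    description: str = ""

    def __post_init__(self):
        if not self.kraus.is_complete():
            raise ContractError("context channel must be trace-preserving")

    @classmethod
    def identity(cls, labels: Sequence[str], description: str = "identity") -> "ContextMap":
        ident = LinearOperator.identity(tuple(labels))
        return cls(
            KrausInstrument(operators=((ident,),), outcome_labels=("id",)),
            description=description,
        )


def apply_context(rho: DensityOperator, ctx: ContextMap) -> DensityOperator:
    """ρ_C′ = ℰ_C′(ρ) = Σ K ρ K†, a valid density operator."""
    if tuple(rho.labels) != ctx.kraus.basis:
        raise ContractError("context and state must share a basis")
    out = np.zeros_like(rho.matrix)
    for K in ctx.kraus.as_channel_matrices():
        out = out + K @ rho.matrix @ K.conj().T
    # symmetrize tiny numerical asymmetry before validation
    out = (out + out.conj().T) / 2.0
    return DensityOperator(rho.labels, out)


def _check_complete_orthogonal(projectors: Sequence[LinearOperator]) -> None:
    if len(projectors) == 0:
        raise ValueError("need at least one projector")
    dim = projectors[0].dim
    total = np.zeros((dim, dim), dtype=complex)
    for P in projectors:
        if not P.is_projector():
            raise ContractError("all operators must be projectors")
        total += P.matrix
    if not np.allclose(total, np.eye(dim), atol=PROBABILITY_TOL, rtol=0):
        raise ContractError("projector set is not complete (ΣΠᵢ ≠ I)")
    for i, P in enumerate(projectors):
        for Q in projectors[i + 1 :]:
            if not np.allclose(P.matrix @ Q.matrix, 0.0, atol=PROBABILITY_TOL):
                raise ContractError("projectors are not mutually orthogonal")


def contextual_probability(
    rho: DensityOperator,
    projectors: Sequence[LinearOperator],
    ctx: ContextMap,
) -> list[float]:
    """Contextual Born rule P(aᵢ|C′) = Tr(ρ_C′ Πᵢ) over a complete set.

    With the identity context this is bit-identical to the standard Born
    rule Tr(ρΠᵢ) (context reduction).
    """
    _check_complete_orthogonal(projectors)
    rho_ctx = apply_context(rho, ctx)
    probs = [float(np.trace(rho_ctx.matrix @ P.matrix).real) for P in projectors]
    total = sum(probs)
    if abs(total - 1.0) > PROBABILITY_TOL:
        raise ContractError(f"contextual probabilities sum to {total}, not 1")
    return probs


def instrument_update(
    rho: DensityOperator, M: LinearOperator
) -> tuple[DensityOperator, float]:
    """Single-outcome measurement update.

    Returns (ρ′, p) with p = Tr(ρM†M) and ρ′ = MρM†/p.  A zero-probability
    outcome raises an explicit error rather than producing NaNs.  For a
    projective M on a pure state this is textbook collapse.
    """
    if tuple(rho.labels) != tuple(M.labels):
        raise ContractError("state and measurement operator must share a basis")
    effect = M.matrix.conj().T @ M.matrix
    p = float(np.trace(rho.matrix @ effect).real)
    if p <= STRUCTURAL_TOL:
        raise ContractError(
            "outcome has zero probability on this state; no update exists"
        )
    post = M.matrix @ rho.matrix @ M.matrix.conj().T / p
    post = (post + post.conj().T) / 2.0
    return DensityOperator(rho.labels, post), p


def qbist_mixture_update(
    p: Sequence[float], r: np.ndarray, d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Dimension-weighted belief update q(j) = ((d+1)/d) Σᵢ p(i) r(j|i).

    ``p`` is the agent's prior over i, ``r[i, j]`` the conditional response
    distribution r(j|i), and ``d`` the Hilbert-space dimension entering the
    (d+1)/d weighting.  Returns ``(literal, normalized)``: the literal
    weighted mixture (which sums to (d+1)/d, not 1) and its normalization.
    As d → ∞ the weight tends to 1 and the literal form approaches the
    classical mixture Σᵢ p(i) r(j|i).
    """
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    if d < 1:
        raise ValueError("d must be a positive dimension")
    if p.ndim != 1 or r.ndim != 2 or r.shape[0] != p.size:
        raise ValueError("r must be a (len(p), n_outcomes) matrix")
    if (p < 0).any() or abs(p.sum() - 1.0) > PROBABILITY_TOL:
        raise ValueError("p must be a probability distribution")
    if (r < 0).any() or not np.allclose(r.sum(axis=1), 1.0, atol=PROBABILITY_TOL):
        raise ValueError("rows of r must be probability distributions")
    literal = (d + 1) / d * (p @ r)
    return literal, literal / literal.sum()


def contextual_observable(U: LinearOperator, Q_obs: LinearOperator) -> LinearOperator:
    """Context-modified observable Â_C = Û Q̂_obs Û†.

    ``U`` must be unitary (validated to structural tolerance); conjugation
    preserves the spectrum while rotating the measurement basis into the
    context's frame.
    """
    if not U.is_unitary():
        raise ContractError("context transformation must be unitary")
    if tuple(U.labels) != tuple(Q_obs.labels):
        raise ContractError("U and Q_obs must share a basis")
    return LinearOperator(U.labels, U.matrix @ Q_obs.matrix @ U.matrix.conj().T)


def collapse_instrument(
    Gamma: LinearOperator,
    t: float,
    projectors: Sequence[LinearOperator],
    outcome_labels: Sequence[str] | None = None,
) -> KrausInstrument:
    """Absorb non-Hermitian decay into measurement operators Mᵢ = e^{−Γ̂t}Πᵢ.

    ``Gamma`` uses the amplitude-rate convention of the collapse engine
    (amplitudes decay as e^{−γt}); in the probability-rate convention
    Γ̃ = 2Γ̂ the same operators read e^{−Γ̃t/2}Πᵢ.  On a state diagonal in
    the decay basis, Tr(ρMᵢ†Mᵢ) reproduces the collapse engine's raw
    |aᵢ(t)|² = |aᵢ(0)|²e^{−2γᵢt} exactly.  The instrument is subnormalized
    for t > 0 (decay leaks probability), mirroring the norm loss of the
    non-unitary evolution.
    """
    if not Gamma.is_positive_semidefinite():
        raise ContractError("Gamma must be Hermitian positive semidefinite")
    if t < 0:
        raise ValueError("t must be >= 0")
    damp = expm(-Gamma.matrix * t)
    if outcome_labels is None:
        outcome_labels = tuple(f"a{i}" for i in range(len(projectors)))
    ops = tuple(
        (LinearOperator(Gamma.labels, damp @ P.matrix),) for P in projectors
    )
    return KrausInstrument(
        operators=ops,
        outcome_labels=tuple(outcome_labels),
        subnormalized=True,
    )
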