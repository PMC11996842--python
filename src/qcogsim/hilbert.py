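"""Finite-dimensional complex Hilbert-space primitives.

Everything else in :mod:`qcogsim` is built on the three containers defined
here: :class:`StateVector` (a labelled ket), :class:`LinearOperator` (a
labelled square matrix) and :class:`DensityOperator` (a validated density
matrix).  Basis compatibility between objects is checked by *label equality*,
not merely by dimension, so a system-space operator can never be silently
applied to an observer-space state.

Tolerances
----------
Two centralized defaults are used throughout the package:

``STRUCTURAL_TOL = 1e-10``
    for structural predicates (hermiticity, idempotency, normalization).
``PROBABILITY_TOL = 1e-8``
    for probabilistic identities (completeness of projector sets, trace
    preservation of channels).

Every ``is_*`` predicate accepts an explicit ``tol`` so callers can tighten
or relax the check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "STRUCTURAL_TOL",
    "PROBABILITY_TOL",
    "StateVector",
    "LinearOperator",
    "DensityOperator",
    "make_state",
    "born_probability",
    "projector_from_state",
    "tensor",
    "BasisMismatchError",
    "DegenerateStateError",
    "ContractError",
]

STRUCTURAL_TOL = 1e-10
PROBABILITY_TOL = 1e-8


class BasisMismatchError(ValueError):
    """Raised when two objects live on different labelled bases."""


class DegenerateStateError(ValueError):
    """Raised when a state has (numerically) zero norm."""


class ContractError(ValueError):
    """Raised when an operator fails a structural pre-condition."""


def _as_labels(labels: Iterable[str]) -> tuple[str, ...]:
    out = tuple(str(x) for x in labels)
    if len(out) == 0:
        raise ValueError("basis must contain at least one label")
    if len(set(out)) != len(out):
        raise ValueError(f"basis labels must be unique, got {out}")
    return out


def _coerce_amplitude(a) -> complex:
    """Accept a complex number or a ``(magnitude, phase_rad)`` pair."""
    if isinstance(a, (tuple, list)):
        if len(a) != 2:
            raise ValueError("amplitude pair must be (magnitude, phase_rad)")
        mag, phase = float(a[0]), float(a[1])
        return mag * complex(np.cos(phase), np.sin(phase))
    return complex(a)


def _check_same_basis(a_labels: Sequence[str], b_labels: Sequence[str]) -> None:
    if tuple(a_labels) != tuple(b_labels):
        raise BasisMismatchError(
            f"basis mismatch: {tuple(a_labels)} vs {tuple(b_labels)}"
        )


@dataclass(frozen=True)
class StateVector:
    """A ket over a labelled orthonormal basis.

    Parameters
    ----------
    labels
        Ordered basis-state names, e.g. ``("B", "F")``.
    amplitudes
        One complex amplitude per label (dimensionless).
    """

    labels: tuple[str, ...]
    amplitudes: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "labels", _as_labels(self.labels))
        amps = np.asarray(self.amplitudes, dtype=complex).reshape(-1)
        if amps.shape[0] != len(self.labels):
            raise ValueError(
                f"{amps.shape[0]} amplitudes for {len(self.labels)} labels"
            )
        amps.setflags(write=False)
        object.__setattr__(self, "amplitudes", amps)

    @property
    def dim(self) -> int:
        return len(self.labels)

    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def is_normalized(self, tol: float = STRUCTURAL_TOL) -> bool:
        return abs(self.norm() ** 2 - 1.0) <= tol

    def normalized(self) -> "StateVector":
        n = self.norm()
        if n <= 1e-300:
            raise DegenerateStateError("cannot normalize a zero state vector")
        return StateVector(self.labels, self.amplitudes / n)

    def inner(self, other: "StateVector") -> complex:
        """⟨self|other⟩ (antilinear in ``self``)."""
        _check_same_basis(self.labels, other.labels)
        return complex(np.vdot(self.amplitudes, other.amplitudes))

    def amplitude(self, label: str) -> complex:
        return complex(self.amplitudes[self.labels.index(label)])


@dataclass(frozen=True)
class LinearOperator:
    """A square complex matrix acting on a labelled basis."""

    labels: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "labels", _as_labels(self.labels))
        mat = np.asarray(self.matrix, dtype=complex)
        d = len(self.labels)
        if mat.shape != (d, d):
            raise ValueError(f"matrix shape {mat.shape} != ({d}, {d})")
        mat.setflags(write=False)
        object.__setattr__(self, "matrix", mat)

    @property
    def dim(self) -> int:
        return len(self.labels)

    def dagger(self) -> "LinearOperator":
        return LinearOperator(self.labels, self.matrix.conj().T)

    def is_hermitian(self, tol: float = STRUCTURAL_TOL) -> bool:
        return bool(np.allclose(self.matrix, self.matrix.conj().T, atol=tol, rtol=0))

    def is_positive_semidefinite(self, tol: float = STRUCTURAL_TOL) -> bool:
        if not self.is_hermitian(tol):
            return False
        eig = np.linalg.eigvalsh(self.matrix)
        return bool(eig.min() >= -tol)

    def is_projector(self, tol: float = STRUCTURAL_TOL) -> bool:
        if not self.is_hermitian(tol):
            return False
        return bool(
            np.allclose(self.matrix @ self.matrix, self.matrix, atol=tol, rtol=0)
        )

    def is_unitary(self, tol: float = STRUCTURAL_TOL) -> bool:
        ident = np.eye(self.dim)
        return bool(
            np.allclose(self.matrix.conj().T @ self.matrix, ident, atol=tol, rtol=0)
        )

    def apply(self, state: StateVector) -> StateVector:
        _check_same_basis(self.labels, state.labels)
        return StateVector(self.labels, self.matrix @ state.amplitudes)

    def __matmul__(self, other: "LinearOperator") -> "LinearOperator":
        _check_same_basis(self.labels, other.labels)
        return LinearOperator(self.labels, self.matrix @ other.matrix)

    def __add__(self, other: "LinearOperator") -> "LinearOperator":
        _check_same_basis(self.labels, other.labels)
        return LinearOperator(self.labels, self.matrix + other.matrix)

    def __sub__(self, other: "LinearOperator") -> "LinearOperator":
        _check_same_basis(self.labels, other.labels)
        return LinearOperator(self.labels, self.matrix - other.matrix)

    def __mul__(self, scalar: complex) -> "LinearOperator":
        return LinearOperator(self.labels, self.matrix * complex(scalar))

    __rmul__ = __mul__

    @classmethod
    def identity(cls, labels: Iterable[str]) -> "LinearOperator":
        labels = _as_labels(labels)
        return cls(labels, np.eye(len(labels)))


@dataclass(frozen=True)
class DensityOperator:
    """A density matrix: Hermitian, positive semidefinite, unit trace."""

    labels: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "labels", _as_labels(self.labels))
        mat = np.asarray(self.matrix, dtype=complex)
        d = len(self.labels)
        if mat.shape != (d, d):
            raise ValueError(f"matrix shape {mat.shape} != ({d}, {d})")
        if not np.allclose(mat, mat.conj().T, atol=STRUCTURAL_TOL, rtol=0):
            raise ContractError("density operator must be Hermitian")
        if abs(np.trace(mat).real - 1.0) > STRUCTURAL_TOL:
            raise ContractError(
                f"density operator trace {np.trace(mat).real} != 1"
            )
        if np.linalg.eigvalsh(mat).min() < -STRUCTURAL_TOL:
            raise ContractError("density operator must be positive semidefinite")
        mat.setflags(write=False)
        object.__setattr__(self, "matrix", mat)

    @property
    def dim(self) -> int:
        return len(self.labels)

    @classmethod
    def from_state(cls, state: StateVector) -> "DensityOperator":
        if not state.is_normalized():
            raise ContractError("state must be normalized to form a pure density")
        a = state.amplitudes
        return cls(state.labels, np.outer(a, a.conj()))

    def as_operator(self) -> LinearOperator:
        return LinearOperator(self.labels, self.matrix)


def make_state(
    labels: Iterable[str],
    amplitudes: Sequence,
    normalize: bool = False,
) -> StateVector:
    """Build a :class:`StateVector` from labels and amplitudes.

    Amplitudes may be complex numbers or ``(magnitude, phase_rad)`` pairs.
    With ``normalize=True`` the vector is rescaled to unit norm; otherwise it
    must already be normalized (within :data:`STRUCTURAL_TOL`).

    Raises
    ------
    DegenerateStateError
        if all amplitudes are zero.
    ContractError
        if ``normalize=False`` and the vector is not normalized.
    """
    amps = [_coerce_amplitude(a) for a in amplitudes]
    state = StateVector(tuple(labels), np.asarray(amps))
    if state.norm() <= 1e-300:
        raise DegenerateStateError("all-zero amplitude vector")
    if normalize:
        return state.normalized()
    if not state.is_normalized():
        raise ContractError(
            f"state norm² = {state.norm()**2:.3e} != 1; pass normalize=True"
        )
    return state


def born_probability(state: StateVector, projector: LinearOperator) -> float:
    """Born-rule probability ⟨ψ|Π|ψ⟩ of the outcome projector Π.

    The pure-state form of Tr(ρΠ); for a rank-1 projector |v⟩⟨v| this is
    |⟨v|ψ⟩|².
    """
    if not state.is_normalized():
        raise ContractError("Born rule requires a normalized state")
    if not projector.is_projector():
        raise ContractError("operator is not a projector (Π² ≠ Π or Π ≠ Π†)")
    _check_same_basis(state.labels, projector.labels)
    a = state.amplitudes
    p = float(np.real(a.conj() @ projector.matrix @ a))
    # guard against tiny negative round-off
    return min(max(p, 0.0), 1.0)


def projector_from_state(state: StateVector) -> LinearOperator:
    """Rank-1 projector |ψ⟩⟨ψ| onto a normalized state."""
    if not state.is_normalized():
        raise ContractError("projector requires a normalized state")
    a = state.amplitudes
    return LinearOperator(state.labels, np.outer(a, a.conj()))


_Kind = Union[StateVector, LinearOperator]


def tensor(a: _Kind, b: _Kind) -> _Kind:
    """Kronecker product of two states or two operators.

    Labels of the product basis are ``"x⊗y"`` pairs; the dimension is the
    product of the operand dimensions.  Mixing a state with an operator is a
    ``TypeError`` — lift the state to a projector first if that is intended.
    """
    pair_labels = tuple(
        f"{la}⊗{lb}" for la in a.labels for lb in b.labels
    )
    if isinstance(a, StateVector) and isinstance(b, StateVector):
        return StateVector(pair_labels, np.kron(a.amplitudes, b.amplitudes))
    if isinstance(a, LinearOperator) and isinstance(b, LinearOperator):
        return LinearOperator(pair_labels, np.kron(a.matrix, b.matrix))
    raise TypeError(
        f"cannot tensor {type(a).__name__} with {type(b).__name__}"
    )
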