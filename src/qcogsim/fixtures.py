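"""Seeded random fixtures for property tests.

Deterministic per (seed, kind, dim, scale): every generator draws from a
fresh ``numpy.random.default_rng(seed)``, so identical specs give
byte-identical objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hilbert import LinearOperator, StateVector
from .qbism import KrausInstrument

__all__ = ["FixtureSpec", "generate_fixture"]

_KINDS = ("hermitian", "psd", "unitary", "state", "cptp")


@dataclass(frozen=True)
class FixtureSpec:
    dim: int
    seed: int
    kind: str
    scale: float = 1.0

    def __post_init__(self):
        if not (2 <= self.dim <= 12):
            raise ValueError("dim must be in [2, 12]")
        if self.kind not in _KINDS:
            raise ValueError(f"unsupported kind {self.kind!r}; one of {_KINDS}")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


def _labels(dim: int) -> tuple[str, ...]:
    return tuple(f"s{k}" for k in range(dim))


def _random_complex(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


def generate_fixture(spec: FixtureSpec):
    """Return a random object satisfying its kind's structural predicate.

    kinds: ``hermitian`` / ``psd`` / ``unitary`` → LinearOperator,
    ``state`` → normalized StateVector, ``cptp`` → trace-preserving
    KrausInstrument (3 Kraus operators via an isometry with orthonormal
    columns).
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.dim
    labels = _labels(d)

    if spec.kind == "hermitian":
        A = _random_complex(rng, (d, d))
        return LinearOperator(labels, spec.scale * (A + A.conj().T) / 2.0)

    if spec.kind == "psd":
        B = _random_complex(rng, (d, d))
        return LinearOperator(labels, spec.scale * (B @ B.conj().T) / d)

    if spec.kind == "unitary":
        Q, R = np.linalg.qr(_random_complex(rng, (d, d)))
        # fix the phase convention so the draw is unique
        Q = Q @ np.diag(np.diag(R) / np.abs(np.diag(R)))
        return LinearOperator(labels, Q)

    if spec.kind == "state":
        v = _random_complex(rng, d)
        return StateVector(labels, v / np.linalg.norm(v))

    # cptp: K_i are the d×d blocks of an isometry V (V†V = I)
    n_kraus = 3
    G = _random_complex(rng, (d * n_kraus, d))
    V, _ = np.linalg.qr(G)
    ops = tuple(
        (LinearOperator(labels, V[i * d : (i + 1) * d, :]),)
        for i in range(n_kraus)
    )
    return KrausInstrument(
        operators=ops,
        outcome_labels=tuple(f"k{i}" for i in range(n_kraus)),
    )
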