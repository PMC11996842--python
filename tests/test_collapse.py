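"""Non-Hermitian collapse engine: closed forms, matrix-exponential oracle,
interference algebra, Zeno suppression."""

import math

import numpy as np
import pytest

from qcogsim.collapse import (
    NonHermitianSystem,
    analytic_amplitudes,
    build_targeted_collapse_operator,
    build_total_hamiltonian,
    conjunction_amplitude,
    evolve,
    interference_cross_term,
    probabilities_with_interference,
    zeno_suppression_ratio,
)
from qcogsim.hilbert import ContractError, LinearOperator, StateVector, tensor

from .conftest import random_hermitian, random_psd, random_state


def random_diagonal_system(seed: int, dim: int = 3) -> NonHermitianSystem:
    rng = np.random.default_rng(seed)
    a0 = rng.standard_normal(dim) + 1j * rng.standard_normal(dim)
    a0 /= np.linalg.norm(a0)
    return NonHermitianSystem(
        labels=tuple(f"s{k}" for k in range(dim)),
        lam=rng.uniform(-2, 2, dim),
        gamma=rng.uniform(0, 1.5, dim),
        a0=a0,
    )


class TestTotalHamiltonian:
    def _parts(self, seed=0, d_sys=2, d_obs=2, psd_scale=1.0):
        H_sys = random_hermitian(d_sys, seed)
        H_obs = random_hermitian(d_obs, seed + 1)
        Gamma = random_psd(d_sys, seed + 2, scale=psd_scale)
        Gamma = LinearOperator(H_sys.labels, Gamma.matrix)
        H_int_small = tensor(random_hermitian(d_sys, seed + 3), random_hermitian(d_obs, seed + 4))
        return H_sys, Gamma, H_obs, H_int_small

    def test_unitary_limit_is_hermitian(self):
        H_sys, _, H_obs, H_int = self._parts()
        zero = LinearOperator(H_sys.labels, np.zeros((2, 2)))
        zero_int = LinearOperator(H_int.labels, np.zeros((4, 4)))
        total = build_total_hamiltonian(H_sys, zero, H_obs, zero_int)
        assert total.is_hermitian(1e-10)

    def test_diagonal_inputs_give_additive_diagonal(self):
        lam = np.array([1.0, 0.5])
        gam = np.array([0.2, 0.4])
        mu = np.array([0.3, 0.7])
        labels_s, labels_o = ("a", "b"), ("u", "d")
        H_sys = LinearOperator(labels_s, np.diag(lam))
        Gamma = LinearOperator(labels_s, np.diag(gam))
        H_obs = LinearOperator(labels_o, np.diag(mu))
        zero_int = LinearOperator(
            tensor(H_sys, H_obs).labels, np.zeros((4, 4))
        )
        total = build_total_hamiltonian(H_sys, Gamma, H_obs, zero_int)
        expected = np.diag(
            [lam[i] - 1j * gam[i] + mu[j] for i in range(2) for j in range(2)]
        )
        np.testing.assert_allclose(total.matrix, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_anti_hermitian_part_is_minus_i_gamma(self, seed):
        """(H − H†)/2 must equal −i(Γ⊗I) exactly."""
        H_sys, Gamma, H_obs, H_int = self._parts(seed)
        total = build_total_hamiltonian(H_sys, Gamma, H_obs, H_int)
        anti = (total.matrix - total.matrix.conj().T) / 2
        I_obs = np.eye(2)
        np.testing.assert_allclose(
            anti, -1j * np.kron(Gamma.matrix, I_obs), atol=1e-12
        )

    def test_non_psd_gamma_rejected(self):
        H_sys, _, H_obs, H_int = self._parts()
        bad = LinearOperator(H_sys.labels, np.diag([-0.5, 1.0]))
        with pytest.raises(ContractError):
            build_total_hamiltonian(H_sys, bad, H_obs, H_int)


class TestTargetedCollapse:
    def test_two_level_shape(self):
        G = build_targeted_collapse_operator(2, 0, 1.0)
        np.testing.assert_allclose(G.matrix, np.diag([0.0, 1.0]))

    def test_three_level_shape(self):
        G = build_targeted_collapse_operator(3, 2, 0.5)
        np.testing.assert_allclose(G.matrix, np.diag([0.5, 0.5, 0.0]))
        assert G.is_positive_semidefinite()

    def test_long_time_collapse_to_target(self):
        """Under −iΓ̂ alone the reported target probability → 1."""
        G = build_targeted_collapse_operator(4, 1, 0.8)
        psi0 = random_state(4, 11)
        psi0 = StateVector(G.labels, psi0.amplitudes)
        gen = LinearOperator(G.labels, -1j * G.matrix)
        res = evolve(gen, psi0, [0.0, 40.0])
        assert res.reported_probabilities[1, 1] == pytest.approx(1.0, abs=1e-9)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            build_targeted_collapse_operator(3, 5, 1.0)


class TestAnalyticAmplitudes:
    def test_flat_system_is_constant(self):
        sys = NonHermitianSystem(("a", "b"), [0, 0], [0, 0], [1 / math.sqrt(2)] * 2)
        res = analytic_amplitudes(sys, np.linspace(0, 5, 7))
        np.testing.assert_allclose(
            res.amplitudes, np.tile(sys.a0, (7, 1)), atol=1e-14
        )

    def test_halving_time(self):
        """γ = 1 at t = ln 2 halves every amplitude magnitude."""
        sys = NonHermitianSystem(
            ("a", "b"), [0.3, -0.2], [1.0, 1.0], [0.6, 0.8]
        )
        res = analytic_amplitudes(sys, [math.log(2.0)])
        np.testing.assert_allclose(
            np.abs(res.amplitudes[0]), [0.3, 0.4], atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_matrix_exponential_oracle(self, seed):
        """Closed form ≡ expm evolution on random diagonal systems (1e−10)."""
        sys = random_diagonal_system(seed)
        times = np.linspace(0.0, 3.0, 5)
        closed = analytic_amplitudes(sys, times)
        psi0 = StateVector(sys.labels, sys.a0)
        general = evolve(sys.generator(), psi0, times)
        np.testing.assert_allclose(
            closed.amplitudes, general.amplitudes, atol=1e-10
        )

    def test_norm_nonincreasing(self):
        for seed in range(20):
            sys = random_diagonal_system(seed)
            res = analytic_amplitudes(sys, np.linspace(0, 4, 40))
            assert (np.diff(res.norm) <= 1e-12).all()


class TestEvolve:
    def test_zero_hamiltonian_is_identity(self):
        psi0 = random_state(3, 5)
        H = LinearOperator(psi0.labels, np.zeros((3, 3)))
        res = evolve(H, psi0, [0.0, 1.0, 10.0])
        np.testing.assert_allclose(
            res.amplitudes, np.tile(psi0.amplitudes, (3, 1)), atol=1e-14
        )

    @pytest.mark.parametrize("seed", range(100))
    def test_hermitian_evolution_preserves_norm(self, seed):
        """Γ = 0 ⇒ unitary dynamics: ‖ψ(t)‖ = 1 to 1e−9."""
        H = random_hermitian(3, seed)
        psi0 = random_state(3, seed + 1000)
        res = evolve(H, psi0, [0.5, 2.0, 7.0])
        np.testing.assert_allclose(res.norm, 1.0, atol=1e-9)

    def test_irreversibility_with_decay(self):
        """For γ > 0 no later time reproduces the initial distribution."""
        sys = random_diagonal_system(3)
        assert sys.gamma.min() >= 0 and sys.gamma.max() > 0
        res = analytic_amplitudes(sys, np.linspace(0.05, 5, 60))
        init = np.abs(sys.a0) ** 2
        for k in range(len(res.times)):
            assert not np.allclose(res.raw_probabilities[k], init, atol=1e-6)


class TestInterference:
    def test_fully_constructive(self):
        assert conjunction_amplitude(1 / math.sqrt(2), 1 / math.sqrt(2)) == (
            pytest.approx(1.0)
        )

    def test_fully_destructive(self):
        assert conjunction_amplitude(0.5, -0.5) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_modulus_expansion_oracle(self, seed):
        """|a₂|² = ½(|a₁|² + |a₃|² + 2Re(a₁a₃*))."""
        rng = np.random.default_rng(seed)
        a1, a3 = (complex(*rng.standard_normal(2)) for _ in range(2))
        lhs = abs(conjunction_amplitude(a1, a3)) ** 2
        rhs = 0.5 * (abs(a1) ** 2 + abs(a3) ** 2 + 2 * (a1 * a3.conjugate()).real)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_t0_equal_amplitudes_fully_constructive(self):
        sys = NonHermitianSystem(
            ("F", "F∧BT", "BT"),
            [0, 0, 0],
            [0, 0, 0],
            [1 / math.sqrt(2), 0, 1 / math.sqrt(2)],
        )
        res = probabilities_with_interference(sys, [0.0])
        assert res.raw_probabilities[0, 1] == pytest.approx(1.0)

    def test_cross_term_constant_when_rates_equal(self):
        """Δλ = Δγ = 0 reduces the cross term to 2Re(a₁(0)a₃*(0))e^{−2γt}."""
        sys = NonHermitianSystem(
            ("x", "x∧y", "y"),
            [0.7, 0.7, 0.7],
            [0.3, 0.3, 0.3],
            np.array([0.6, 0.0, 0.8j]),
        )
        for t in (0.0, 0.5, 2.0):
            expected = 2 * (sys.a0[0] * np.conj(sys.a0[2])).real * math.exp(
                -2 * 0.3 * t
            )
            assert interference_cross_term(sys, t) == pytest.approx(
                expected, abs=1e-12
            )

    def test_slow_state_dominates_at_long_times(self):
        """γ_y ≫ γ_x ⇒ P(x) dominates the late-time distribution."""
        sys = NonHermitianSystem(
            ("x", "x∧y", "y"),
            [1.0, 0.6, 0.2],
            [0.05, 0.5, 2.0],
            [0.6, 0.0, 0.8],
        )
        res = probabilities_with_interference(sys, [8.0])
        assert res.reported_probabilities[0, 0] > 0.6
        assert res.reported_probabilities[0, 0] == max(
            res.reported_probabilities[0]
        )

    def test_bt_subtraction_can_go_negative_raw_but_not_reported(self):
        sys = NonHermitianSystem(
            ("F", "F∧BT", "BT"),
            [1.2, 0.7, 0.2],
            [0.1, 0.3, 0.6],
            [1 / math.sqrt(2), 0, 1 / math.sqrt(2)],
        )
        res = probabilities_with_interference(sys, np.linspace(0, 3, 30))
        assert res.raw_probabilities[:, 2].min() < 0
        assert (res.reported_probabilities >= 0).all()
        np.testing.assert_allclose(
            res.reported_probabilities.sum(axis=1), 1.0, atol=1e-12
        )


class TestZeno:
    def _sys(self, gamma_scale):
        return NonHermitianSystem(
            ("t", "n1", "n2"),
            [0.0, 0.0, 0.0],
            np.array([0.0, 1.0, 1.0]) * gamma_scale,
            [0.5, 0.5, math.sqrt(0.5)],
        )

    def test_no_decay_no_suppression(self):
        assert zeno_suppression_ratio(self._sys(0.0), 2.0) == pytest.approx(1.0)

    def test_monotone_in_gamma(self):
        r1 = zeno_suppression_ratio(self._sys(1.0), 1.5)
        r2 = zeno_suppression_ratio(self._sys(2.0), 1.5)
        assert r2 < r1 < 1.0

    def test_complete_suppression_limit(self):
        assert zeno_suppression_ratio(self._sys(50.0), 5.0) == pytest.approx(
            0.0, abs=1e-12
        )
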