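"""Fail-proof conjugate residual solver: convergence, bookkeeping,
conditioning, and singular-system behavior."""

import numpy as np
import pytest

from aimpol.errors import InputError
from aimpol.fcr import condition_system, fcr_solve
from aimpol.fixtures import SpectrumSpec, make_hermitian_system

from conftest import random_symmetric


class TestConditionSystem:
    def test_identity_conditioner_passthrough(self):
        a, b = random_symmetric(8, 1)
        m_op, w, back = condition_system(a, b)
        assert np.allclose(m_op(b), a @ b)
        assert np.array_equal(w, b)
        assert np.array_equal(back(w), w)

    def test_diagonal_conditioner_matches_dense_congruence(self):
        a, b = random_symmetric(10, 2)
        c = np.random.default_rng(3).uniform(0.5, 2.0, 10)
        m_op, w, back = condition_system(a, b, conditioner=c)
        m_dense = np.array([m_op(e) for e in np.eye(10)]).T
        assert np.allclose(m_dense, (c[:, None] * a) * c[None, :])
        assert np.allclose(m_dense, m_dense.T)     # Hermitian by construction
        assert np.allclose(w, c * b)
        # back-transform solves the original system
        x = back(np.linalg.solve(m_dense, w))
        assert np.allclose(a @ x, b, atol=1e-9)

    def test_initial_guess_shift(self):
        a, b = random_symmetric(6, 4)
        x0 = np.random.default_rng(5).standard_normal(6)
        m_op, w, back = condition_system(a, b, x0=x0)
        assert np.allclose(w, b - a @ x0)
        assert np.allclose(back(np.zeros(6)), x0)

    def test_singular_conditioner_rejected(self):
        a, b = random_symmetric(4, 6)
        with pytest.raises(InputError):
            condition_system(a, b, conditioner=np.array([1.0, 0.0, 1, 1]))


class TestConvergence:
    def test_identity_converges_in_one_iteration(self):
        r = fcr_solve(np.eye(7), np.arange(1.0, 8.0), tol=1e-12)
        assert r.status == "consistent"
        assert r.iterations == 1
        assert np.allclose(r.y, np.arange(1.0, 8.0))

    def test_twelve_distinct_eigenvalues_need_at_most_six_iterations(self):
        lam = np.repeat(np.linspace(0.5, 1.5, 12), 25)
        m, w, _, _ = make_hermitian_system(
            SpectrumSpec(size=300, eigenvalues=tuple(lam), seed=42))
        r = fcr_solve(m, np.random.default_rng(42).standard_normal(300),
                      tol=1e-12, max_iters=100)
        assert r.status == "consistent"
        assert r.iterations <= 6

    @pytest.mark.parametrize("n", [10, 24, 60])
    def test_exact_arithmetic_termination_bound(self, n):
        """At tight tolerance, random dense symmetric systems converge in at
        most ceiling(Nrows/2) iterations."""
        m, w = random_symmetric(n, n)
        r = fcr_solve(m, w, tol=1e-13, max_iters=10 * n)
        assert r.status == "consistent"
        assert r.iterations <= -(-n // 2)
        assert np.allclose(m @ r.y, w, atol=1e-10)

    @pytest.mark.parametrize("n, seed", [(40, 0), (80, 1), (150, 2), (200, 3)])
    def test_agrees_with_dense_direct_solve(self, n, seed):
        m, w = random_symmetric(n, seed)
        tol = 1e-11
        r = fcr_solve(m, w, tol=tol, max_iters=20 * n)
        x = np.linalg.solve(m, w)
        assert r.status == "consistent"
        assert np.max(np.abs(m @ (r.y - x))) < 10 * tol

    def test_indefinite_spectrum_converges(self):
        """Mixed-sign eigenvalues (where Orthomin's <z|Mz> denominator can
        vanish) pose no problem."""
        lam = np.concatenate([np.linspace(-2.0, -0.4, 20),
                              np.linspace(0.4, 2.0, 20)])
        m, w, x_true, _ = make_hermitian_system(
            SpectrumSpec(size=40, eigenvalues=tuple(lam), seed=8))
        r = fcr_solve(m, w, tol=1e-11, max_iters=400)
        assert r.status == "consistent"
        assert np.allclose(r.y, x_true, atol=1e-8)

    def test_monotone_gamma_decrease_every_iteration(self):
        for seed in (1, 2, 3):
            m, w = random_symmetric(50, seed + 100)
            r = fcr_solve(m, w, tol=1e-13, max_iters=500)
            hist = r.residual_history
            assert all(b < a for a, b in zip(hist, hist[1:]))

    def test_max_iterations_status(self):
        m, w = random_symmetric(60, 77)
        r = fcr_solve(m, w, tol=1e-13, max_iters=3)
        assert r.status == "max_iterations"
        assert r.iterations == 3


class TestSingularSystems:
    def test_trivial_inconsistent_example(self):
        r = fcr_solve(np.diag([1.0, 0.0]), np.array([1.0, 1.0]), tol=1e-10)
        assert r.status == "inconsistent"
        assert np.allclose(r.y, [1.0, 0.0])

    def test_singular_consistent_solved_orthogonal_to_kernel(self):
        lam = (0.0, 0.0) + tuple(np.linspace(0.5, 2.0, 48))
        spec = SpectrumSpec(size=50, eigenvalues=lam, kernel_dim=2, seed=9)
        m, w, x_true, kernel = make_hermitian_system(spec)
        r = fcr_solve(m, w, tol=1e-10, max_iters=300)
        assert r.status == "consistent"
        assert np.max(np.abs(m @ r.y - w)) < 1e-9
        for k in kernel.T:
            assert abs(r.y @ k) < 1e-8

    def test_inconsistent_least_squares_residual_is_kernel_component(self):
        lam = (0.0,) + tuple(np.linspace(0.5, 2.0, 49))
        spec = SpectrumSpec(size=50, eigenvalues=lam, kernel_dim=1, seed=10)
        amp = 0.37
        m, w, _, _ = make_hermitian_system(spec, inconsistent_amp=amp)
        r = fcr_solve(m, w, tol=1e-10, max_iters=300)
        assert r.status == "inconsistent"
        assert np.linalg.norm(m @ r.y - w) == pytest.approx(amp, rel=1e-6)


class TestBookkeeping:
    def test_four_matvecs_per_steady_state_iteration(self):
        m, w = random_symmetric(80, 55)
        r = fcr_solve(m, w, tol=1e-12, max_iters=400)
        assert r.iterations >= 5
        steady = r.matvecs_per_iteration[1:-1]
        assert all(c == 4 for c in steady)

    def test_one_iteration_identity_solve_has_bounded_startup_cost(self):
        r = fcr_solve(np.eye(4), np.ones(4), tol=1e-12)
        assert r.iterations == 1
        assert r.matvec_count <= 4

    def test_mz_recurrence_tracks_direct_product(self):
        """The recurrence-updated M z stays close to a directly computed
        M @ z while the residual is meaningfully large."""
        m, w = random_symmetric(50, 123)
        r = fcr_solve(m, w, tol=1e-13, max_iters=300, audit=True)
        hist = np.asarray(r.residual_history)
        relerrs = r.audit["mz_recurrence_relerr"]
        for gamma, relerr in zip(hist[:len(relerrs)], relerrs):
            if gamma > 1e-12 * hist[0]:
                assert relerr < 1e-10

    def test_direction_image_orthogonality_audit(self):
        m, w = random_symmetric(60, 321)
        r = fcr_solve(m, w, tol=1e-12, max_iters=300, audit=True)
        norm = np.sqrt(r.residual_history[0])
        for key in ("mp_mq_orth", "pp_prev_orth", "qq_prev_orth"):
            assert max(r.audit[key], default=0.0) < 1e-8 * norm * norm

    def test_round_off_resistance_under_perturbation(self):
        """Gamma still decreases monotonically when the operator output
        carries injected low-amplitude noise."""
        m, w = random_symmetric(40, 9)
        rng = np.random.default_rng(0)

        def noisy(v):
            out = m @ v
            return out + 1e-13 * np.linalg.norm(out) \
                * rng.standard_normal(len(out))

        r = fcr_solve(noisy, w, tol=1e-9, max_iters=200)
        hist = r.residual_history
        assert all(b < a for a, b in zip(hist, hist[1:]))
        assert r.status == "consistent"
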