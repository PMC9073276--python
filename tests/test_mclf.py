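"""Inverse-free incremental screening: single-step accuracy orders,
Richardson extrapolation, the anisotropic correction, and pipeline
invariants."""

import numpy as np
import pytest

from aimpol.fixtures import dense_incremental_screening, make_crystal
from aimpol.mclf import (richardson_extrapolate, run_mclf, screening_pass,
                         screened_with_res, static_anisotropic_correction)
from aimpol.pairs import build_pair_lists, build_region_grid
from aimpol.system import RunConfig

ALPHA0 = np.array([12.0, 8.0])
CUTOFF = 50.0


@pytest.fixture
def dimer_lists(dimer):
    grid = build_region_grid(dimer, CUTOFF)
    return build_pair_lists(dimer, grid, ALPHA0, CUTOFF)


def _init_tensors(alpha0):
    return alpha0[:, None, None] * np.eye(3)


class TestScreeningPass:
    def test_isolated_atom_is_a_fixed_point(self, isolated_atom):
        grid = build_region_grid(isolated_atom, CUTOFF)
        lists = build_pair_lists(isolated_atom, grid, np.array([12.0]),
                                 CUTOFF)
        for mode, init in (("nondir", np.array([12.0])),
                           ("fluctuating", _init_tensors(np.array([12.0]))),
                           ("static", _init_tensors(np.array([12.0])))):
            out = screening_pass(init, lists, 0.25, mode=mode)
            assert np.array_equal(out, init)

    def test_pass_matches_dense_first_order_oracle(self, dimer, dimer_lists):
        """The list-based engine reproduces an independently written dense
        single-Schulz-step iteration to machine precision."""
        for delta in (1.0, 0.25):
            prod = screening_pass(_init_tensors(ALPHA0), dimer_lists, delta,
                                  mode="fluctuating")
            ref = dense_incremental_screening(dimer, ALPHA0, CUTOFF, delta,
                                              exact=False)
            assert np.max(np.abs(prod - ref)) < 1e-12

    def test_per_increment_error_scales_as_delta_squared(self, dimer):
        errs = []
        deltas = (0.5, 0.25, 0.125, 0.0625)
        for delta in deltas:
            exact = dense_incremental_screening(dimer, ALPHA0, CUTOFF, delta,
                                                exact=True, nsteps=1)
            first = dense_incremental_screening(dimer, ALPHA0, CUTOFF, delta,
                                                exact=False, nsteps=1)
            errs.append(np.max(np.abs(exact - first)))
        ratios = [a / b for a, b in zip(errs, errs[1:])]
        for r in ratios:
            assert 3.0 < r < 5.0     # halving delta quarters the error

    def test_per_pass_error_scales_as_delta(self, dimer, dimer_lists):
        limit = dense_incremental_screening(dimer, ALPHA0, CUTOFF, 2.0 ** -8,
                                            exact=True)
        errs = []
        for xi in range(0, 5):
            p = screening_pass(_init_tensors(ALPHA0), dimer_lists, 2.0 ** -xi,
                               mode="fluctuating")
            errs.append(np.max(np.abs(p - limit)))
        ratios = [a / b for a, b in zip(errs, errs[1:])]
        for r in ratios:
            assert 1.5 < r < 2.5     # halving delta halves the error


class TestRichardson:
    def test_equal_passes_return_the_same_value(self):
        assert richardson_extrapolate([7.7] * 4, 3) == pytest.approx(7.7)

    def test_polynomial_error_annihilated_exactly(self):
        truth = 3.0
        vals = [truth + 2.0 * (2.0 ** -k) + 5.0 * (2.0 ** -k) ** 2
                for k in range(3)]
        assert richardson_extrapolate(vals, 2) == pytest.approx(truth,
                                                                abs=1e-12)

    def test_extrapolation_beats_every_single_pass(self, dimer, dimer_lists):
        limit = dense_incremental_screening(dimer, ALPHA0, CUTOFF, 2.0 ** -8,
                                            exact=True)
        passes = [screening_pass(_init_tensors(ALPHA0), dimer_lists,
                                 2.0 ** -xi, mode="fluctuating")
                  for xi in range(6)]
        extrap = richardson_extrapolate(passes, 5)
        err_single = min(np.max(np.abs(p - limit)) for p in passes)
        err_extrap = np.max(np.abs(extrap - limit))
        assert err_extrap < err_single / 10

    def test_high_order_limit_matches_dense_inversion_protocol(
            self, dimer, dimer_lists):
        """K = 7 extrapolated screening agrees with the dense exact-update
        reference to ~1e-4 relative on the two-atom toy."""
        extrap = screened_with_res(_init_tensors(ALPHA0), dimer_lists, 7,
                                   mode="fluctuating")
        limit = dense_incremental_screening(dimer, ALPHA0, CUTOFF, 2.0 ** -9,
                                            exact=True)
        rel = np.max(np.abs(extrap - limit)) / np.max(np.abs(limit))
        assert rel < 1e-4


class TestAnisotropicCorrection:
    def test_zero_factor_returns_input(self):
        t = np.array([[3.0, 0.2, 0], [0.2, 2.0, 0], [0, 0, 1.0]])
        out = static_anisotropic_correction(t, 2.0, correction_factor=0.0)
        assert np.allclose(out, t)

    def test_isotropic_tensor_is_a_fixed_point(self):
        t = 4.0 * np.eye(3)
        out = static_anisotropic_correction(t, 3.0)
        assert np.allclose(out, t)

    def test_symmetric_trace_preserving_amplification(self):
        t = np.array([[5.0, 0.5, 0.1], [0.5, 3.0, 0.2], [0.1, 0.2, 2.5]])
        out = static_anisotropic_correction(t, 3.0)
        assert np.allclose(out, out.T)
        assert np.trace(out) == pytest.approx(np.trace(t))
        dev_in = t - np.trace(t) / 3 * np.eye(3)
        dev_out = out - np.trace(out) / 3 * np.eye(3)
        assert np.linalg.norm(dev_out) > np.linalg.norm(dev_in)


class TestPipeline:
    def test_static_output_identities_and_nonnegativity(self, dimer):
        cfg = RunConfig(res_nondir=3, res_static=3)
        res = run_mclf(dimer, cfg)
        assert np.array_equal(res.alpha_forcefield,
                              res.alpha_nondir_u[:, -1])
        assert np.array_equal(res.alpha_low_freq,
                              res.alpha_screened_iso_u[:, -1])
        assert np.all(res.alpha_forcefield >= 0)
        assert np.all(res.alpha_low_freq >= 0)
        assert np.all(res.alpha_static_iso >= 0)
        assert np.all(res.c6_atom >= 0)

    def test_supercell_invariance_of_engine_outputs(self):
        cfg = RunConfig(res_nondir=3, res_static=3)
        prim = make_crystal("rocksalt", seed=1)
        sup = make_crystal("rocksalt", repeat=(2, 2, 2), seed=1)
        r1 = run_mclf(prim, cfg)
        r2 = run_mclf(sup, cfg)
        for attr in ("alpha_forcefield", "alpha_low_freq",
                     "alpha_static_iso", "c6_atom"):
            a = np.tile(getattr(r1, attr), 8)
            b = getattr(r2, attr)
            assert np.max(np.abs(a - b)) < 1e-8, attr

    def test_screening_reduces_isotropic_polarizability(self, dimer):
        res = run_mclf(dimer, RunConfig(res_nondir=3, res_static=3))
        assert np.all(res.alpha_forcefield < res.unscreened.alpha0)
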