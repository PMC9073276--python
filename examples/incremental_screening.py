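"""Inverse-free incremental screening with Richardson extrapolation.

Screens a two-atom molecule by switching the dipole coupling on in J = 1/D
increments (each a first-order Schulz-step contraction, so no matrix is
ever inverted) and compares against a dense exact-update reference.  The
pass error shrinks linearly in the increment size D; Richardson
extrapolation over passes with D = 1, 1/2, ..., 2^-K removes successive
powers of D and converges far faster than any single pass.
"""

import numpy as np

from aimpol.fixtures import dense_incremental_screening
from aimpol.mclf import richardson_extrapolate, screening_pass
from aimpol.pairs import build_pair_lists, build_region_grid
from aimpol.system import AtomicSystem

dimer = AtomicSystem(elements=("C", "N"),
                     coordinates=np.array([[0.0, 0, 0], [4.5, 0, 0]]),
                     lattice_vectors=np.zeros((3, 3)),
                     periodic_flags=(False,) * 3,
                     r3_moments=np.array([14.0, 11.0]))
alpha0 = np.array([12.0, 8.0])
cutoff = 50.0
lists = build_pair_lists(dimer, build_region_grid(dimer, cutoff),
                         alpha0, cutoff)
init = alpha0[:, None, None] * np.eye(3)

reference = dense_incremental_screening(dimer, alpha0, cutoff, 2.0 ** -9,
                                        exact=True)
print("screening a C-N dimer, fluctuating (tensor) mode; errors vs a dense")
print("exact-update reference (max |tensor difference|, a.u.):\n")
print(f"{'Delta':>8} {'pass error':>12}")
passes = []
for xi in range(6):
    delta = 2.0 ** -xi
    p = screening_pass(init, lists, delta, mode="fluctuating")
    passes.append(p)
    print(f"{delta:>8.5f} {np.max(np.abs(p - reference)):>12.3e}")

for k in (2, 5):
    extrap = richardson_extrapolate(passes[:k + 1], k)
    print(f"Richardson K={k}: {np.max(np.abs(extrap - reference)):>12.3e}")
print("\nhalving Delta halves the single-pass error; extrapolation removes")
print("those error powers wholesale.")
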