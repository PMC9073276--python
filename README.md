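# aimpol

Linear-scaling computation of **atom-in-material (AIM) polarizabilities and
C6 dispersion coefficients** for molecules and materials with 0–3 periodic
directions.

Force-field developers and dispersion-correction users need per-atom static
polarizability tensors α_A and homo-atomic dispersion coefficients C6,A that
reflect each atom's chemical environment. Starting from AIM ⟨r³⟩ radial
moments (produced upstream by an electron-density partitioning code), the
Tkatchenko–Scheffler scaling law sets unscreened per-atom values, and
self-consistent screening (TS-SCS) then couples all atoms through the
Gaussian-damped dipole–dipole interaction: for a unit external field
**E**⁰ along each Cartesian direction one solves

    μ_A,s / α_A(u) + Σ_b τ_st^{Ab}(u) μ_b,t = E⁰_A,s ,

a real symmetric linear system of 3·N_atoms rows per imaginary-frequency
point u, whose induced dipoles assemble the screened AIM tensors. C6,A
follows from the Casimir–Polder integral
C6 = (3/π)∫₀^∞ α(iω)² dω evaluated on a 2^G-point Romberg grid.

What makes the package scale linearly in the atom count:

- **spatial-region pair lists** — translation-symmetry-unique interacting
  pairs are found by decomposing the (enclosing) cell into regions smaller
  than the 50-bohr dipole cutoff sphere; a *small* list catalogs pairs with
  overlapping Gaussian dipole densities (d ≤ 5^{4/3}·σ_AB, the only ones
  that need the erf-damped kernel) and a *large* list stores, per unique
  pair, the bare dipole tensor pre-summed over **all** periodic images
  within the cutoff;
- a **matrix-free conditioned operator** — the coefficients matrix is never
  assembled; one application walks the two lists once;
- the **fail-proof conjugate residual (FCR)** solver — a two-direction-per-
  iteration Krylov method that minimizes the conditioned residual norm for
  *any* Hermitian matrix (definite, indefinite, or singular), decreases the
  residual monotonically, costs exactly four operator applications per
  steady-state iteration, and converges in at most ⌈Ξ/2⌉ iterations for Ξ
  distinct eigenvalues;
- an **inverse-free incremental screening engine** — screening switched on
  in increments Δ with a single Schulz-step contraction per increment
  (per-pass error O(Δ)) and Richardson extrapolation over
  Δ = 1, 1/2, …, 2^{-K} (residual error O(Δ^{K+1}));
- a **logarithmic wp lookup table** — the total C6 over all unordered atom
  pairs via the London-type mixing formula
  C6,AB = (3/2)·α_Aα_B·wp_Awp_B/(wp_A+wp_B), computed in O(N) by
  scattering each atom's α onto two ln(wp)-adjacent table nodes; the
  unsigned relative error is bounded by interval²/16 ≈ 4·Num_lookup⁻², and
  totals are accumulated with compensated (extended-precision) summation.

## Worked example

```bash
python examples/tsscs_crystal.py
```

prints (atomic units):

```
primitive cell (2 atoms), all values in atomic units
atom elem  alpha_unscr  alpha_SCS   C6_unscr     C6_SCS
   1   Na     144.7775    67.2861  1232.0730   479.6701
   2   Cl      19.4973     4.0028   159.8296   119.4746
cell C6 total over unordered pairs (itemized): 56.2708
FCR iterations: max 1 per solve, 48 total, 150 matrix-vector multiplies

2x2x2 supercell (16 atoms): per-atom alpha drift vs primitive = 4.41e-13
```

Reading it: screening in the dense rock-salt lattice *reduces* both atoms'
polarizabilities relative to their unscreened (isolated-atom-scaled)
values — the sodium site from 144.8 to 67.3 a.u. — and the C6 coefficients
shrink with them, since C6 tracks the square of the fluctuating
polarizability. The conditioned systems converge in a single FCR iteration
per field direction and frequency (48 solves in total), and the per-atom
results from a 2×2×2 supercell match the primitive cell to 13 digits:
the image-summed pair lists treat the infinite crystal exactly the same
way at both cell sizes. The other scripts in `examples/` each demonstrate
one capability (pair lists, the FCR solver on definite/indefinite/singular
spectra, the lookup-table total, incremental screening with Richardson
extrapolation).

The library is import-first (`aimpol.run_tsscs`, `aimpol.run_mclf`,
`aimpol.fcr_solve`, …); a thin `aimpol` command-line wrapper is installed
for shell use (`aimpol tsscs --xyz system.xyz`, `aimpol c6total --csv
atoms.csv`, `aimpol fcr --matrix M.mtx --rhs b.txt`, `aimpol fixtures`).
Input files are extended xyz (element, x, y, z in Å, per-atom ⟨r³⟩ in
a.u., optional `Lattice="..."` and `pbc="T T F"` header fields) plus an
optional `calculation_parameters.txt` of `key = value` lines.

## Scope

The package takes AIM ⟨r³⟩ moments as *input*; computing them from electron
densities is upstream partitioning work. The incremental screening engine
ships with engine-validated defaults for the non-directional pair
contraction and the multibody screening weight (identity); both are
injectable hooks, and chemistry-specific choices (smooth cutoff functions,
m-scaling unscreened models, conduction limits, higher-order C8/C9/C10
coefficients) are out of scope. See `docs/methods.md` for the model,
numerical choices, and limitations.
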