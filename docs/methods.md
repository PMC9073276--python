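# Methods

This note records the models, algorithms, parameter choices and numerical
conventions the package implements, and what its synthetic test surface
does and does not establish.

## Model and units

Everything internal is in Hartree atomic units; only the extended-xyz
reader/writer converts lengths from/to angstroms (1 Å = 1.8897259886 bohr).

Per-atom inputs are AIM ⟨r³⟩ radial moments. The Tkatchenko–Scheffler
scaling law maps them onto unscreened values through a free-atom reference
table: α_A = α_free·(⟨r³⟩_AIM/⟨r³⟩_free) and C6,A = C6_free·(ratio)².
The characteristic one-pole frequency wp_A = 4·C6,A/(3·α_A²) is invariant
under this scaling, and makes the one-pole (Padé) dynamic polarizability
α(iω) = α(0)/(1+(ω/wp)²), the Casimir–Polder integral, and the London
mixing formula C6,AB = (3/2)α_Aα_B wp_Awp_B/(wp_A+wp_B) mutually
consistent: the formula's self-limit (3/4)α²wp reproduces C6,AA exactly,
and for A≠B it equals the exact Casimir–Polder integral of the one-pole
product (verified in the tests against 50-digit quadrature).

The shipped free-atom table (`data/free_atom_reference.csv`) carries
literature-style free-atom α and C6 values; the ⟨r³⟩_free column is an
exact closed form only for hydrogen and representative elsewhere, and the
table is replaceable via the `reference=` argument. No test depends on its
values — tests inject synthetic reference entries.

Each atom carries a spherical Gaussian dipole density of width
σ = (sqrt(2/π)·α/3)^{1/3}; a pair is damped over σ_AB = sqrt(σ_A²+σ_B²).
The interaction kernel is the second position-derivative of erf(d/σ_AB)/d,
which reduces to the bare point-dipole tensor η/d³
(η_st = 3Δ_sΔ_t/d² − δ_st, symmetric and traceless) as σ→0. The sign and
normalization convention is pinned operationally: in the screening system
A·μ = E⁰ with A = diag(1/α_A) + τ blocks, two collinear atoms polarize
more along the bond than across it, and the full two-atom solve matches a
dense direct-inverse oracle.

## Pair lists

The enclosing parallelepiped keeps periodic lattice vectors as basis
vectors; each non-periodic direction gets a perpendicular vector spanning
the nuclei plus one dipole-cutoff length of padding on each side, so every
region-membership test is well defined. The cell is divided into whole
numbers of regions per basis vector with edges at most one cutoff long
(hence region volume below the cutoff-sphere volume); empty regions are
skipped. Interacting region-pair images are pre-filtered with a
conservative center-distance-minus-half-diagonals bound — overestimating
region pairs is harmless because every candidate atom pair is distance-
tested individually.

Pairs are stored once each using the translation-uniqueness criteria
(different atom indices, or a lexicographically positive translation for
self pairs) with the convention first-index ≤ second-index. The small list
keeps one record per overlapping image (d ≤ 5^{4/3}·σ_AB evaluated with
the *static* unscreened α, built once and reused at every frequency); the
large list keeps one record per unique pair with Σ f_cut·η/d³ accumulated
over **all** images within the cutoff (self-pair records fold in both
mirror images). The operator and the screening engine treat a small-list
record as the *correction* (damped − bare) on top of the large list's bare
sums, so the expensive erf evaluations happen only for overlapping pairs
and no image sum is ever recomputed. The cutoff constant 5^{4/3} ≈ 8.5499
guarantees the neglected damping correction is below erfc(5) ≈ 1.5e-12
even if screening quintuples α (σ ∝ α^{1/3}). The cutoff function is a
pluggable hook; the default is the sharp step at the 50-bohr cutoff.

Correctness of the whole construction is established against a brute-force
O(N²·images) enumeration oracle on molecular, 2-D and 3-D periodic
fixtures, and the lists are invariant to region-granularity refinement.

## The FCR solver

The conditioned system M y = W (M = C A C^H, C = diag(sqrt(α_A(u))), so
diagonal blocks are the identity and eigenvalues cluster near one) is
solved by the fail-proof conjugate residual method. Each iteration spends
two search directions generated from the running residual image M z and
kept conjugate in the ⟨M·|M·⟩ inner product; the leading step coefficient
is ⟨Mp|z⟩/⟨Mp|Mp⟩ = ‖Mz‖²/‖Mp‖² > 0 regardless of the sign structure of
the spectrum — the failure mode of Orthomin-type conjugate gradients
(division by ⟨z|Mz⟩, which can vanish for indefinite M) cannot occur, and
Γ = ⟨z|z⟩ decreases strictly every iteration. Division-by-zero protection
sets any coefficient with a vanishing ⟨Mp|Mp⟩- or ⟨Mq|Mq⟩-type denominator
to zero, its correct limiting value.

Structurally the iteration is a conjugate-residual sweep on the positive-
semidefinite operator M² with y = M·s: all search directions are odd
polynomials in M applied to W, one iteration extends the chain by two
powers of M² (to M^{4i−1}W), and the steady-state cost is exactly four
operator applications per iteration — M applied to each assembled
direction, and M applied to each direction image, the latter pair also
refreshing M z through the recurrence
Mz^{(i)} = Mz^{(i−1)} − γ M²p^{(i)} − τ M²q^{(i)} (re-verified directly
before any inconsistency declaration). Because y never leaves the range of
M, singular-but-consistent systems are solved exactly with y ⊥ kernel(M),
and inconsistent ones converge to the least-squares minimizer with the
kernel part of W left in the residual. Exact-arithmetic consequences —
termination in ⌈Ξ/2⌉ iterations for Ξ distinct represented eigenvalues and
⌈N/2⌉ in general — are preserved in floating point by re-orthogonalizing
each new direction against the full stored set (the default; a
`reorth_pairs` window reproduces the fixed-memory short-recurrence profile
at some cost in round-off resistance and finite-termination sharpness).

Exits, tested in order each iteration: (1) consistent when every
|z-component| < tol (default 1e-5, the production convergence criterion);
(2) inconsistent when ‖Mz‖ < mz_tol (default 1e-10·‖W‖) *and*
‖Mz‖ ≤ 1e-3·‖z‖ — the second clause distinguishes an exhausted reachable
residual from ordinary convergence at tight tolerances, since conditioned
consistent systems keep ‖Mz‖ ~ ‖z‖; (3) max_iterations (default 1000; a
small cap with tiny tolerances gives the fixed-iteration mode used in
polarizable-force-field dynamics).

The 12-distinct-eigenvalue convergence fixture uses eigenvalues
linspace(0.5, 1.5) with multiplicity 25: the clustering near one emulates
what the diagonal conditioning produces on physical systems, and at
tolerance 1e-12 the ⌈12/2⌉ = 6-iteration bound is then met in floating
point; widely spread spectra (ratio ≳ 10 in λ²) leave a round-off floor of
~1e-11 at the bound, visible only below tolerances ~1e-11.

## TS-SCS pipeline

Per imaginary-frequency point u and per Cartesian field direction, the
conditioned system is solved with W = sqrt(α(u)) replicated unit fields;
the back-transformed induced dipoles form the columns of each atom's
screened 3×3 tensor. Successive solves start from y = 0 (the conditioning
shift forces this); warm starting is deliberately not used. The static
tensor is the u = 1 (zero-frequency) solve, symmetrized; per-atom C6 comes
from Casimir–Polder integration of the isotropic dynamic values; cell
totals sum atomic tensors and feed the screened (α, wp) pairs to the C6
total machinery. A dense GEPP path (`use_direct_inversion`, guarded to
small systems) provides the direct-inversion protocol used by the
equivalence tests. Bookkeeping reports the maximum single-solve iteration
count, the total over all 3·2^G solves, and total operator applications.

## Frequency grid and quadrature

The Casimir–Polder integral is mapped by u = 1/(1+ω) (both limits finite;
u = 0 is infinite frequency, where the one-pole α ∝ 1/ω² makes the
transformed integrand vanish exactly, so that endpoint is dropped). The
2^G interior points carry order-(G,G) Romberg weights computed
programmatically by Richardson-extrapolating the nested trapezoid rules —
never hard-coded, and checked against a hand tableau at G = 1 and by exact
integration of cubics at G = 2. The default G = 4 (16 points) leaves a
relative quadrature error of a few 1e-5 for order-unity wp (1e-5 at
wp = 1; ~2e-5 at wp = 0.5, degrading toward extreme wp, the same pattern
the integration-order convergence of heavy-alkali solids shows). This
quadrature error is also why an isolated atom's integrated C6 matches its
closed-form unscreened value to ~1e-4 relative rather than exactly.

## Incremental screening engine

One pass applies J = 1/Δ increments; each increment recomputes σ_AB from
the current isotropic polarizabilities and applies the single Schulz-step
contraction (per-atom update in the header of `aimpol/mclf.py`). Mixed
A–B contributions are partitioned proportionally to the atoms' current
isotropic polarizabilities. Modes: `nondir` (scalars; coupling =
tr(τ)/3 = (4/(3√π))·υ³e^{−υ²}/d³ over the small list) → force-field
polarizability at u = 1; `fluctuating` (tensors, damped kernel over the
small list) → dynamic screened values and C6; `static` (tensors,
small-list damping correction plus large-list bare image sums) → the
long-range static tensor. Richardson extrapolation uses fixed increments
Δ = 2^{1−ξ} per pass, with defaults of 5 steps for the non-directional and
fluctuating screenings and 7 for the static one (the static response has
the longest-ranged couplings and needs the extra orders). Extrapolation
coefficients come from the same programmatic tableau as the quadrature
weights (coefficients sum to one; polynomial error terms annihilated
exactly, which the tests check symbolically on model sequences).

The dense oracles integrate one increment either exactly (inverting the
incremented coefficients matrix with GEPP) or to first order; the engine
matches the first-order oracle to machine precision, the exact/first-order
gap contracts as Δ² per increment and Δ per pass, and K-step extrapolation
beats every single pass — these measured orders are the engine's
correctness argument.

The static anisotropic correction amplifies the deviatoric part of the
static tensor, corrected = t + C.F.·(α_low_freq/α_static_iso)·dev(t), with
correction factor 0.2. The functional form is this package's own choice
within the stated contracts (zero factor = identity; isotropic tensors are
fixed points; symmetry and trace preserved); like the non-directional
contraction and the unit multibody weight, it is an *engine default*:
outputs under these defaults validate the algorithmic machinery, not a
specific dispersion chemistry. Chemistry-specific hooks (`mbs_weight`,
`cutoff_fn`, reference tables) are injectable.

Non-negativity of the isotropic outputs holds on all shipped fixtures and
is asserted, but is not proven for arbitrary inputs under the engine
defaults; a pass with a very large Δ on pathologically overlapping
geometries can overshoot (the increment then raises a numerical error
rather than propagating negative polarizabilities).

## C6 totals

Itemized totals run over all N(N−1)/2 unordered pairs with row-wise
pairwise summation and Neumaier compensation across rows; the
double-double (sum, compensation) pair loses less than one part in 1e18
over a million like-signed terms, which is what keeps totals meaningful
when they exceed a single pair term by many orders of magnitude. An
optional mpmath mode (50 significant digits) mirrors true quadruple
precision. The lookup table spaces ln(wp) uniformly over
[ln min(wp)−0.01, ln max(wp)+0.01] (the guard keeps the interval non-zero
and the floor index in range); each atom's α is split linearly in ln(wp)
between its two adjacent nodes, values exactly on a node going wholly to
the lower one. The node-versus-atom double sum counts every ordered pair
once including self terms; exact self contributions (3/4)α²wp are
subtracted and the remainder halved. Nodes with zero mass are skipped, so
k symmetry-distinct wp values touch at most 2k nodes. Dispatch: itemized
below threshold_wp_lookup = 2·Num_lookup atoms, lookup above (both
callable directly). Measured URE obeys the interval²/16 bound on every
random trial and sits near 2e-10 at Num_lookup = 1e5 on 1e4 atoms.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| dipole_cutoff | 50 bohr | interaction range; pairs beyond it never couple |
| romberg_order | 4 | 16 imaginary-frequency points |
| fcr_tol | 1e-5 | max abs conditioned-residual component |
| mz_length_tol | 1e-10·‖W‖ | inconsistency threshold on ‖Mz‖ |
| max_cr_steps | 1000 | convergence-seeking iteration cap |
| num_lookup | 1e5 | wp table nodes (URE ≲ 4e-10) |
| threshold_wp_lookup | 2e5 | itemized/lookup dispatch point |
| res_nondir, res_static | 5, 7 | Richardson steps per screening family |

## Synthetic test surface and problem sizes

All test inputs are generated: toy crystals (two-atom rock-salt fcc
primitive cell, 1.42-Å graphene sheet with 2-D periodicity, one-atom cubic
cell), seeded random clusters/boxes of 15–40 atoms, spectrum-controlled
symmetric matrices up to 300 rows, and synthetic (α, C6) populations up to
1e4 atoms. Supercell-invariance checks use 2×2×2 replicas (16 atoms);
screening-order checks use a two-atom molecule where dense references are
exact. These sizes keep the default suite under a minute of solver time
while exercising every code path; they establish algorithmic correctness
(list completeness, solver equivalence to direct inversion, error orders,
precision bounds) — they do not validate chemical accuracy against
measured materials, which would require real AIM moments from upstream
density partitioning. Synthetic ⟨r³⟩ moments are drawn per element from
seeded uniform ranges, so TS scaling is exercised without any literature
value being load-bearing.

## Known limitations

- Periodic self-interaction sums are truncated sharply at the cutoff; no
  Ewald-type treatment of the conditionally convergent tail (static
  polarizabilities of strongly coupled periodic systems inherit the same
  cutoff sensitivity the 50-bohr default implies).
- The full-reorthogonalization FCR default stores all direction triples
  (O(N·iterations) memory); use `reorth_pairs` for very large systems.
- Atom positions are wrapped into the reference cell along periodic
  directions before list construction; reported translation triples refer
  to wrapped positions.
- The engine's chemistry hooks default to engine-validated stand-ins (see
  above); quantitative dispersion work should inject domain-specific
  forms and reference data.
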