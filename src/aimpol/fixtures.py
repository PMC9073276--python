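"""Deterministic synthetic generators and independent dense oracles.

Everything here is a pure function of its parameters and a seed, so test
inputs are reproducible bit-for-bit.  The dense oracles (brute-force image
enumeration, direct GEPP screening solve) are deliberately written as
independent transcriptions of the underlying formulas — they never call the
linear-scaling production paths they are used to validate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .errors import InputError
from .system import AtomicSystem
from .units import BOHR_PER_ANGSTROM

__all__ = ["make_crystal", "random_cluster", "SpectrumSpec",
           "make_hermitian_system", "brute_force_pairs",
           "dense_coefficients_matrix", "dense_screened_tensors"]

# default synthetic <r^3> scales per element (a.u.); anything absent uses 12.0
_R3_BASE = {"H": 6.0, "C": 14.0, "N": 11.0, "O": 9.5, "Na": 85.0, "Cl": 22.0,
            "K": 130.0, "F": 8.0, "X": 12.0}


def _moments(elements, rng):
    return np.array([rng.uniform(0.7, 1.3) * _R3_BASE.get(el, 12.0)
                     for el in elements])


def make_crystal(kind: str, repeat=(1, 1, 1), a: float | None = None,
                 seed: int = 0) -> AtomicSystem:
    """Toy crystals with synthetic AIM moments.

    kinds: ``rocksalt`` (two-atom fcc primitive cell, 3 PBC, default
    a = 5.64 angstrom), ``graphene_sheet`` (two-atom hexagonal cell with
    1.42 angstrom nearest-neighbor C-C, 2-D periodic), ``cubic_toy``
    (one atom, simple cubic, 3 PBC, default a = 4.0 angstrom).
    ``repeat`` replicates the cell; replicated atoms copy the primitive
    atoms' moments so supercells are physically identical.
    """
    rng = np.random.default_rng(seed)
    if kind == "rocksalt":
        a = 5.64 if a is None else a
        lat = 0.5 * a * np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        frac = np.array([[0.0, 0, 0], [0.5, 0.5, 0.5]])
        elements = ["Na", "Cl"]
        pbc = (True, True, True)
    elif kind == "graphene_sheet":
        a = 1.42 * math.sqrt(3.0) if a is None else a
        lat = np.array([[a, 0.0, 0], [-0.5 * a, 0.5 * math.sqrt(3) * a, 0],
                        [0.0, 0, 0]])
        frac = np.array([[0.0, 0, 0], [1 / 3.0, 2 / 3.0, 0]])
        elements = ["C", "C"]
        pbc = (True, True, False)
    elif kind == "cubic_toy":
        a = 4.0 if a is None else a
        lat = a * np.eye(3)
        frac = np.array([[0.0, 0, 0]])
        elements = ["X"]
        pbc = (True, True, True)
    else:
        raise InputError(f"unknown crystal kind {kind!r}")
    if any(x <= 0 for x in (a,)):
        raise InputError("lattice parameter must be positive")

    moments = _moments(elements, rng)
    n1, n2, n3 = repeat
    shifts = np.array([(i, j, k) for i in range(n1) for j in range(n2)
                       for k in range(n3)], dtype=float)
    frac_all = (frac[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    coords = frac_all @ lat * BOHR_PER_ANGSTROM
    lat_super = lat * np.array([n1, n2, n3])[:, None] * BOHR_PER_ANGSTROM
    for k in range(3):
        if not pbc[k]:
            lat_super[k] = 0.0
    return AtomicSystem(
        elements=tuple(elements) * (n1 * n2 * n3),
        coordinates=coords,
        lattice_vectors=lat_super,
        periodic_flags=pbc,
        r3_moments=np.tile(moments, n1 * n2 * n3),
    )


def random_cluster(natoms: int, box: float = 20.0, min_sep: float = 3.0,
                   pbc=(False, False, False), seed: int = 0) -> AtomicSystem:
    """Random atoms in a box (bohr) with a minimum separation, optionally
    periodic.  Elements cycle through a small set; moments are synthetic."""
    rng = np.random.default_rng(seed)
    coords = []
    tries = 0
    lat = box * np.eye(3)
    while len(coords) < natoms:
        cand = rng.uniform(0, box, 3)
        ok = True
        for c in coords:
            d = cand - c
            for k in range(3):
                if pbc[k]:
                    d[k] -= box * round(d[k] / box)
            if np.linalg.norm(d) < min_sep:
                ok = False
                break
        if ok:
            coords.append(cand)
        tries += 1
        if tries > 200 * natoms:
            raise InputError("cannot place atoms with the requested spacing")
    elements = tuple(np.take(["C", "N", "O", "H"], np.arange(natoms) % 4))
    for k in range(3):
        if not pbc[k]:
            lat[k] = 0.0
    return AtomicSystem(elements=elements, coordinates=np.array(coords),
                        lattice_vectors=lat, periodic_flags=tuple(pbc),
                        r3_moments=_moments(elements, rng))


@dataclass(frozen=True)
class SpectrumSpec:
    """Request for a symmetric matrix with an exact spectrum."""

    size: int
    eigenvalues: tuple              # multiset, len == size
    kernel_dim: int = 0
    seed: int = 0


def make_hermitian_system(spec: SpectrumSpec, inconsistent_amp: float = 0.0):
    """Symmetric matrix with the requested spectrum plus a right-hand side.

    The matrix is Q^T diag(lambda) Q for a seeded random orthogonal Q.  The
    rhs is built as M x_true (hence consistent and orthogonal to the
    kernel); ``inconsistent_amp`` adds that multiple of a kernel basis
    vector, making the least-squares residual norm exactly its magnitude.

    Returns ``(matrix, rhs, x_true, kernel_basis)``.
    """
    lam = np.asarray(spec.eigenvalues, dtype=float)
    if lam.size != spec.size:
        raise InputError("need one eigenvalue per row")
    if np.count_nonzero(lam == 0.0) != spec.kernel_dim:
        raise InputError("kernel_dim must match the zero eigenvalue count")
    rng = np.random.default_rng(spec.seed)
    q, _ = np.linalg.qr(rng.standard_normal((spec.size, spec.size)))
    order = np.argsort(lam == 0.0)     # zeros last; their q-columns = kernel
    lam = lam[order]
    m = (q * lam) @ q.T
    m = 0.5 * (m + m.T)
    x_true = rng.standard_normal(spec.size)
    if spec.kernel_dim:
        kernel = q[:, spec.size - spec.kernel_dim:]
        x_true -= kernel @ (kernel.T @ x_true)
    else:
        kernel = np.zeros((spec.size, 0))
    rhs = m @ x_true
    if inconsistent_amp:
        if not spec.kernel_dim:
            raise InputError("inconsistency needs a nontrivial kernel")
        rhs = rhs + inconsistent_amp * kernel[:, 0]
    return m, rhs, x_true, kernel


# ---------------------------------------------------------------------------
# dense oracles
# ---------------------------------------------------------------------------

def _image_range(system: AtomicSystem, cutoff: float):
    lat = system.lattice_vectors
    span = np.ptp(system.coordinates, axis=0).sum() + 1.0
    lmax = []
    for k in range(3):
        if not system.periodic_flags[k]:
            lmax.append(0)
            continue
        others = [j for j in range(3) if j != k and system.periodic_flags[j]]
        if len(others) == 2:
            area = np.linalg.norm(np.cross(lat[others[0]], lat[others[1]]))
            height = abs(np.linalg.det(lat[[k] + others])) / area
        elif len(others) == 1:
            u = lat[others[0]] / np.linalg.norm(lat[others[0]])
            height = np.linalg.norm(lat[k] - (lat[k] @ u) * u)
        else:
            height = np.linalg.norm(lat[k])
        lmax.append(math.ceil((cutoff + span) / height) + 1)
    return lmax


def brute_force_pairs(system: AtomicSystem, unscreened_alphas, cutoff: float,
                      upsilon_cutoff: float = 5.0 ** (4.0 / 3.0)):
    """O(N^2 x images) enumeration of the unique small/large pair catalogs.

    Returns ``(small, large)``: ``small`` is a sorted list of
    (A, B, L1, L2, L3, d) tuples; ``large`` maps (A, B) -> summed bare
    eta/d^3 six-component array over all images within the cutoff
    (self pairs include both mirror images).
    """
    alphas = np.asarray(unscreened_alphas, dtype=float)
    sig = (math.sqrt(2.0 / math.pi) * alphas / 3.0) ** (1.0 / 3.0)
    lat = system.lattice_vectors
    coords = system.coordinates
    n = system.natoms
    lmax = _image_range(system, cutoff)
    small = []
    large = {}
    six = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    for a in range(n):
        for b in range(a, n):
            sigma_ab = math.sqrt(sig[a] ** 2 + sig[b] ** 2)
            for l1 in range(-lmax[0], lmax[0] + 1):
                for l2 in range(-lmax[1], lmax[1] + 1):
                    for l3 in range(-lmax[2], lmax[2] + 1):
                        L = (l1, l2, l3)
                        if a == b and not (L > (0, 0, 0)):
                            continue
                        delta = coords[a] - (coords[b] + np.array(L) @ lat)
                        d = float(np.linalg.norm(delta))
                        if d > cutoff:
                            continue
                        mult = 2.0 if a == b else 1.0
                        eta = np.array(
                            [3.0 * delta[s] * delta[t] / d ** 2 - (s == t)
                             for s, t in six])
                        acc = large.setdefault((a, b), np.zeros(6))
                        acc += mult * eta / d ** 3
                        if d <= upsilon_cutoff * sigma_ab:
                            small.append((a, b, l1, l2, l3, d))
    return sorted(small), large


def _oracle_tau(delta, sigma):
    """Independent transcription of -d2/dr2 [erf(d/sigma)/d] as a 3x3 block."""
    d = float(np.linalg.norm(delta))
    if sigma == 0.0:
        fp_over_r = -1.0 / d ** 3
        curv = 3.0 / d ** 5
    else:
        v = d / sigma
        g = 2.0 / math.sqrt(math.pi) * math.exp(-v * v)
        f = erf(v) / d
        fp = g / (sigma * d) - erf(v) / d ** 2
        fpp = -2.0 * v * g / (sigma ** 2 * d) - 2.0 * g / (sigma * d ** 2) \
            + 2.0 * erf(v) / d ** 3
        del f
        fp_over_r = fp / d
        curv = fpp / d ** 2 - fp / d ** 3
    out = np.empty((3, 3))
    for s in range(3):
        for t in range(3):
            out[s, t] = (s == t) * fp_over_r + delta[s] * delta[t] * curv
    return -out


def dense_coefficients_matrix(system: AtomicSystem, alphas,
                              cutoff: float) -> np.ndarray:
    """Direct assembly of the unconditioned screening matrix A (3N x 3N):
    diagonal blocks I/alpha_A, off-diagonal blocks the erf-damped dipole
    coupling summed over all periodic images within the cutoff.  Brute-force
    image loops, independent of the pair-list machinery."""
    alphas = np.asarray(alphas, dtype=float)
    sig = (math.sqrt(2.0 / math.pi) * alphas / 3.0) ** (1.0 / 3.0)
    n = system.natoms
    lat = system.lattice_vectors
    coords = system.coordinates
    lmax = _image_range(system, cutoff)
    a_mat = np.zeros((3 * n, 3 * n))
    for a in range(n):
        a_mat[3 * a:3 * a + 3, 3 * a:3 * a + 3] = np.eye(3) / alphas[a]
    for a in range(n):
        for b in range(n):
            sigma_ab = math.sqrt(sig[a] ** 2 + sig[b] ** 2)
            block = np.zeros((3, 3))
            for l1 in range(-lmax[0], lmax[0] + 1):
                for l2 in range(-lmax[1], lmax[1] + 1):
                    for l3 in range(-lmax[2], lmax[2] + 1):
                        if a == b and (l1, l2, l3) == (0, 0, 0):
                            continue
                        delta = coords[a] - (coords[b]
                                             + np.array([l1, l2, l3]) @ lat)
                        d = float(np.linalg.norm(delta))
                        if d > cutoff or d == 0.0:
                            continue
                        block += _oracle_tau(delta, sigma_ab)
            a_mat[3 * a:3 * a + 3, 3 * b:3 * b + 3] += block
    return a_mat


def dense_incremental_screening(system: AtomicSystem, alpha0, cutoff: float,
                                delta: float, exact: bool = True,
                                nsteps: int | None = None) -> np.ndarray:
    """Dense reference for one tensor screening pass on a molecular system.

    Runs J = 1/delta increments.  With ``exact=True`` each increment
    contracts the exact inverse of the incremented coefficients matrix
    (GEPP); with ``exact=False`` it applies the first-order (single
    Schulz-step) contraction instead.  Both recompute attenuation lengths
    from the current isotropic polarizabilities each increment, mirror the
    proportional partition of mixed contributions, and are written densely
    and independently of the list-based production engine.  Molecular
    (non-periodic) systems only.
    """
    import scipy.linalg

    if any(system.periodic_flags):
        raise InputError("dense screening oracle covers molecules only")
    n = system.natoms
    coords = system.coordinates
    if nsteps is None:
        nsteps = round(1.0 / delta)
    alphas = np.asarray(alpha0, dtype=float)[:, None, None] * np.eye(3)
    for _ in range(nsteps):
        iso = np.trace(alphas, axis1=1, axis2=2) / 3.0
        sig = (math.sqrt(2.0 / math.pi) * iso / 3.0) ** (1.0 / 3.0)
        tau = np.zeros((3 * n, 3 * n))
        for a in range(n):
            for b in range(n):
                if a == b:
                    continue
                delta_r = coords[a] - coords[b]
                d = float(np.linalg.norm(delta_r))
                if d > cutoff:
                    continue
                sigma_ab = math.sqrt(sig[a] ** 2 + sig[b] ** 2)
                tau[3 * a:3 * a + 3, 3 * b:3 * b + 3] = \
                    _oracle_tau(delta_r, sigma_ab)
        dinv = np.zeros((3 * n, 3 * n))
        for a in range(n):
            dinv[3 * a:3 * a + 3, 3 * a:3 * a + 3] = alphas[a]
        if exact:
            dmat = np.zeros_like(dinv)
            for a in range(n):
                dmat[3 * a:3 * a + 3, 3 * a:3 * a + 3] = \
                    scipy.linalg.inv(alphas[a])
            p = scipy.linalg.inv(dmat + delta * tau)
        else:
            p = dinv - dinv @ (delta * tau) @ dinv
        new = np.empty_like(alphas)
        for a in range(n):
            acc = p[3 * a:3 * a + 3, 3 * a:3 * a + 3].copy()
            for b in range(n):
                if b == a:
                    continue
                frac = iso[a] / (iso[a] + iso[b])
                acc += frac * (p[3 * a:3 * a + 3, 3 * b:3 * b + 3]
                               + p[3 * b:3 * b + 3, 3 * a:3 * a + 3])
            new[a] = 0.5 * (acc + acc.T)
        alphas = new
    return alphas


def dense_screened_tensors(system: AtomicSystem, alphas,
                           cutoff: float) -> np.ndarray:
    """Reference screened tensors by direct GEPP solve of the dense system."""
    import scipy.linalg

    n = system.natoms
    a_mat = dense_coefficients_matrix(system, alphas, cutoff)
    tensors = np.empty((n, 3, 3))
    for t in range(3):
        e0 = np.zeros(3 * n)
        e0[t::3] = 1.0
        mu = scipy.linalg.solve(a_mat, e0)
        tensors[:, :, t] = mu.reshape(n, 3)
    return tensors
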