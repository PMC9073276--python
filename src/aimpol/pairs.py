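"""Linear-scaling construction of the interacting atom-pair lists.

Two catalogs of translation-symmetry-unique atom pairs are built by spatial
region decomposition:

* the **small** list holds pairs whose Gaussian dipole densities overlap,
  i.e. ``d_Ab / sigma_AB(static) <= upsilon_cutoff = 5**(4/3)``; these are the
  only pairs that ever need the (expensive) erf-damped tensor;
* the **large** list holds one record per unique pair (A, B) that has at
  least one periodic image within the dipole interaction cutoff, with the
  bare dipole tensor accumulated over *all* such images, so no sum over
  periodic images is ever repeated downstream.

An image pair ``(A, (B, L1, L2, L3))`` is translation-symmetry unique iff
the atom indices differ, or ``L1 > 0``, or ``L1 = 0 and L2 > 0``, or
``L1 = L2 = 0 and L3 > 0``.  With atom indices ordered ``A <= B`` each
unordered geometric pair is stored exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .system import AtomicSystem, enclosing_parallelepiped

__all__ = [
    "UPSILON_CUTOFF",
    "is_unique_pair",
    "RegionGrid",
    "build_region_grid",
    "SmallList",
    "LargeList",
    "PairLists",
    "build_pair_lists",
    "sharp_cutoff",
]

#: Overlap cutoff 5**(4/3) ~ 8.55: even if screening quintuples alpha
#: (sigma ~ alpha**(1/3)), the neglected erfc tail stays below erfc(5) ~ 1.5e-12.
UPSILON_CUTOFF = 5.0 ** (4.0 / 3.0)

_SIX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def is_unique_pair(atom_a: int, atom_b: int, translation) -> bool:
    """Translation-symmetry uniqueness criteria (i)-(iv)."""
    l1, l2, l3 = translation
    return (atom_a != atom_b) or (l1 > 0) or (l1 == 0 and l2 > 0) \
        or (l1 == 0 and l2 == 0 and l3 > 0)


def sharp_cutoff(d, d_cutoff):
    """Sharp cutoff 1 - H(d - d_cutoff): 1 inside the cutoff, 0 beyond."""
    return np.where(np.asarray(d, float) <= d_cutoff, 1.0, 0.0)


@dataclass
class RegionGrid:
    """Spatial regions of the enclosing parallelepiped plus the interacting
    region-pair-image catalog."""

    basis: np.ndarray                 # (3,3) rows; enclosing parallelepiped
    origin: np.ndarray
    counts: tuple[int, int, int]      # regions along each basis vector
    coords: np.ndarray                # atom positions wrapped into the cell
    region_of_atom: np.ndarray        # flat region index per atom
    order: np.ndarray                 # atom indices sorted by region
    region_slices: dict               # flat region index -> (start, stop) in order
    entries: list                     # (region1, region2, (L1,L2,L3)) interacting
    cutoff: float

    @property
    def occupied_regions(self):
        return sorted(self.region_slices)

    def atoms_in(self, region):
        start, stop = self.region_slices[region]
        return self.order[start:stop]


def _wrap_coords(system: AtomicSystem, basis, origin):
    """Wrap atoms into the reference cell along periodic directions."""
    coords = system.coordinates - origin
    frac = np.linalg.solve(basis.T, coords.T).T
    for k in range(3):
        if system.periodic_flags[k]:
            frac[:, k] -= np.floor(frac[:, k])
        else:
            frac[:, k] = np.clip(frac[:, k], 0.0, np.nextafter(1.0, 0.0))
    return frac @ basis + origin, frac


def build_region_grid(system: AtomicSystem, cutoff: float,
                      subdivide: int = 1) -> RegionGrid:
    """Divide the enclosing parallelepiped into spatial regions and catalog
    the interacting region pair images.

    Each region's volume is below that of a sphere of cutoff radius (edges
    are at most one cutoff long).  ``subdivide`` multiplies the region counts
    along every axis; the resulting pair lists are invariant to it.  Empty
    regions are skipped, so a few atoms in an enormous box stay cheap.
    """
    basis = enclosing_parallelepiped(system, padding=cutoff)
    # Anchor the box at the lowest corner spanned by the nuclei (non-periodic
    # directions only; periodic directions wrap).
    origin = np.zeros(3)
    for k in range(3):
        if not system.periodic_flags[k]:
            u = basis[k] / np.linalg.norm(basis[k])
            proj = system.coordinates @ u
            pad = (np.linalg.norm(basis[k]) - (proj.max() - proj.min())) / 2.0
            origin = origin + (proj.min() - pad) * u
    coords, frac = _wrap_coords(system, basis, origin)

    lengths = np.linalg.norm(basis, axis=1)
    counts = tuple(max(1, math.ceil(L / cutoff)) * subdivide for L in lengths)

    idx3 = np.minimum((frac * counts).astype(int), np.array(counts) - 1)
    flat = (idx3[:, 0] * counts[1] + idx3[:, 1]) * counts[2] + idx3[:, 2]
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    region_slices = {}
    if len(order):
        bounds = np.flatnonzero(np.diff(sorted_flat)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [len(order)]])
        for s, e in zip(starts, stops):
            region_slices[int(sorted_flat[s])] = (int(s), int(e))

    occupied = sorted(region_slices)
    nocc = len(occupied)
    # Region geometry for the (conservative) minimum-distance filter.
    edge = basis / np.array(counts)[:, None]
    half_diag = 0.5 * np.linalg.norm(edge, axis=1).sum()
    occ3 = np.array([
        ((r // counts[2]) // counts[1], (r // counts[2]) % counts[1], r % counts[2])
        for r in occupied
    ]) if nocc else np.zeros((0, 3), int)
    centers = origin + (occ3 + 0.5) @ edge

    # Candidate cell images along periodic directions.
    lmax = []
    vol = abs(np.linalg.det(basis))
    diam = lengths.sum()
    for k in range(3):
        if system.periodic_flags[k]:
            height = vol / np.linalg.norm(np.cross(basis[(k + 1) % 3],
                                                   basis[(k + 2) % 3]))
            lmax.append(math.ceil((cutoff + diam) / height) + 1)
        else:
            lmax.append(0)
    ranges = [np.arange(-m, m + 1) for m in lmax]
    images = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    shifts = images @ basis

    entries = []
    for i in range(nocc):
        for j in range(nocc):
            dvec = centers[j] + shifts - centers[i]
            dmin = np.linalg.norm(dvec, axis=1) - 2.0 * half_diag
            for k in np.flatnonzero(dmin <= cutoff):
                entries.append((occupied[i], occupied[j],
                                tuple(int(t) for t in images[k])))

    return RegionGrid(basis=basis, origin=origin, counts=counts, coords=coords,
                      region_of_atom=flat, order=order,
                      region_slices=region_slices, entries=entries,
                      cutoff=cutoff)


@dataclass
class SmallList:
    """Overlapping ('small') pair records, one per unique image."""

    atom_a: np.ndarray
    atom_b: np.ndarray
    translation: np.ndarray   # (n, 3) int
    d: np.ndarray             # bohr
    f_cut: np.ndarray
    eta: np.ndarray           # (n, 6): 11, 12, 13, 22, 23, 33

    def __len__(self):
        return len(self.atom_a)


@dataclass
class LargeList:
    """Within-cutoff ('large') pair records, image sums pre-accumulated.

    ``bare_sums`` holds sum over images of f_cut * eta_st / d^3 (six unique
    components); self-pairs include both mirror images of every stored
    translation.
    """

    atom_a: np.ndarray
    atom_b: np.ndarray
    bare_sums: np.ndarray     # (n, 6)
    n_images: np.ndarray

    def __len__(self):
        return len(self.atom_a)


@dataclass
class PairLists:
    small: SmallList
    large: LargeList


def _empty_small():
    z = np.zeros(0, dtype=int)
    return SmallList(z, z, np.zeros((0, 3), int), np.zeros(0), np.zeros(0),
                     np.zeros((0, 6)))


def _empty_large():
    z = np.zeros(0, dtype=int)
    return LargeList(z, z, np.zeros((0, 6)), z)


def build_pair_lists(system: AtomicSystem, grid: RegionGrid,
                     unscreened_alphas, cutoff: float,
                     cutoff_fn=None) -> PairLists:
    """Build the small and large lists from the region-pair-image catalog.

    ``unscreened_alphas`` are the static unscreened polarizabilities that fix
    the pair attenuation lengths for the overlap criterion.  ``cutoff_fn`` is
    the smooth-cutoff hook; the default is the sharp step used for TS-SCS.
    """
    from .dipole import pair_sigma

    if cutoff_fn is None:
        cutoff_fn = sharp_cutoff
    alphas = np.asarray(unscreened_alphas, dtype=float)
    if np.any(alphas <= 0):
        raise GeometryError("unscreened alphas must be positive")
    coords = grid.coords
    basis = grid.basis

    sm_rows = {k: [] for k in ("a", "b", "L", "d", "f", "eta")}
    lg_acc = {}   # (a, b) -> [sum6, n_images]

    for r1, r2, L in grid.entries:
        atoms1 = grid.atoms_in(r1) if r1 in grid.region_slices else ()
        atoms2 = grid.atoms_in(r2) if r2 in grid.region_slices else ()
        if len(atoms1) == 0 or len(atoms2) == 0:
            continue
        shift = np.asarray(L) @ basis
        a_idx = np.repeat(atoms1, len(atoms2))
        b_idx = np.tile(atoms2, len(atoms1))
        # Canonical unique candidates only: A < B, or A == B with a
        # lexicographically positive translation.
        if L == (0, 0, 0):
            keep = a_idx < b_idx
        elif L > (0, 0, 0):
            keep = a_idx <= b_idx
        else:
            keep = a_idx < b_idx
        a_idx, b_idx = a_idx[keep], b_idx[keep]
        if len(a_idx) == 0:
            continue
        delta = coords[a_idx] - (coords[b_idx] + shift)
        d = np.linalg.norm(delta, axis=1)
        within = d <= cutoff
        if np.any(d[within] <= 0.0):
            bad = a_idx[within][d[within] <= 0.0][0]
            raise GeometryError(f"coincident nuclei in unique pair (atom {bad + 1})")
        a_w, b_w = a_idx[within], b_idx[within]
        delta_w, d_w = delta[within], d[within]
        if len(a_w) == 0:
            continue
        d2 = d_w * d_w
        eta = np.empty((len(a_w), 6))
        for k, (s, t) in enumerate(_SIX):
            eta[:, k] = 3.0 * delta_w[:, s] * delta_w[:, t] / d2
        eta[:, 0] -= 1.0
        eta[:, 3] -= 1.0
        eta[:, 5] -= 1.0
        fcut = np.asarray(cutoff_fn(d_w, cutoff), dtype=float)

        # Large-list accumulation (self-pairs count both mirror images).
        mult = np.where(a_w == b_w, 2.0, 1.0)
        contrib = (fcut * mult / d_w ** 3)[:, None] * eta
        for i in range(len(a_w)):
            key = (int(a_w[i]), int(b_w[i]))
            acc = lg_acc.get(key)
            if acc is None:
                lg_acc[key] = [contrib[i].copy(), 1]
            else:
                acc[0] += contrib[i]
                acc[1] += 1

        # Small-list overlap criterion with the *static* attenuation length.
        sigma = pair_sigma(alphas[a_w], alphas[b_w])
        overlap = d_w <= UPSILON_CUTOFF * sigma
        if np.any(overlap):
            sm_rows["a"].append(a_w[overlap])
            sm_rows["b"].append(b_w[overlap])
            sm_rows["L"].append(np.broadcast_to(np.asarray(L),
                                                (int(overlap.sum()), 3)).copy())
            sm_rows["d"].append(d_w[overlap])
            sm_rows["f"].append(fcut[overlap])
            sm_rows["eta"].append(eta[overlap])

    if sm_rows["a"]:
        small = SmallList(
            atom_a=np.concatenate(sm_rows["a"]),
            atom_b=np.concatenate(sm_rows["b"]),
            translation=np.concatenate(sm_rows["L"]),
            d=np.concatenate(sm_rows["d"]),
            f_cut=np.concatenate(sm_rows["f"]),
            eta=np.concatenate(sm_rows["eta"]),
        )
        # Group by first atom (cache-friendly contract) with a stable order.
        key = np.lexsort((small.translation[:, 2], small.translation[:, 1],
                          small.translation[:, 0], small.atom_b, small.atom_a))
        small = SmallList(small.atom_a[key], small.atom_b[key],
                          small.translation[key], small.d[key],
                          small.f_cut[key], small.eta[key])
    else:
        small = _empty_small()

    if lg_acc:
        keys = sorted(lg_acc)
        large = LargeList(
            atom_a=np.array([k[0] for k in keys]),
            atom_b=np.array([k[1] for k in keys]),
            bare_sums=np.array([lg_acc[k][0] for k in keys]),
            n_images=np.array([lg_acc[k][1] for k in keys]),
        )
    else:
        large = _empty_large()

    n = system.natoms
    assert len(large) <= n * (n + 1) // 2
    return PairLists(small=small, large=large)


def dump_lists_tsv(lists: PairLists, path) -> None:
    """Debug dump (1-based indices) for oracle comparison."""
    with open(path, "w") as fh:
        fh.write("# small list: A B L1 L2 L3 d eta11 eta12 eta13 eta22 eta23 eta33\n")
        sm = lists.small
        for i in range(len(sm)):
            fh.write(f"{sm.atom_a[i] + 1}\t{sm.atom_b[i] + 1}\t"
                     + "\t".join(str(x) for x in sm.translation[i])
                     + f"\t{sm.d[i]:.12g}\t"
                     + "\t".join(f"{x:.12g}" for x in sm.eta[i]) + "\n")
        fh.write("# large list: A B n_images bare_sums(6)\n")
        lg = lists.large
        for i in range(len(lg)):
            fh.write(f"{lg.atom_a[i] + 1}\t{lg.atom_b[i] + 1}\t{lg.n_images[i]}\t"
                     + "\t".join(f"{x:.12g}" for x in lg.bare_sums[i]) + "\n")
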