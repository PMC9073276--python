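"""Pair-list construction: uniqueness criteria, region decomposition, and
agreement with brute-force image enumeration."""

import math

import numpy as np
import pytest
from scipy.special import erfc

from aimpol.errors import GeometryError
from aimpol.fixtures import brute_force_pairs, make_crystal, random_cluster
from aimpol.pairs import (UPSILON_CUTOFF, build_pair_lists, build_region_grid,
                          is_unique_pair)
from aimpol.system import AtomicSystem


@pytest.mark.parametrize("a, b, L, expected", [
    (3, 7, (-1, 0, 2), True),     # different indices
    (5, 5, (0, 0, 0), False),     # untranslated self pair
    (5, 5, (0, 0, 1), True),      # criterion (iv)
    (5, 5, (0, 0, -1), False),
    (5, 5, (0, 1, -3), True),     # criterion (iii)
    (5, 5, (0, -1, 3), False),
    (5, 5, (1, -5, -5), True),    # criterion (ii)
    (5, 5, (-1, 5, 5), False),
])
def test_uniqueness_criteria(a, b, L, expected):
    assert is_unique_pair(a, b, L) is expected


def test_exactly_one_of_each_mirror_self_pair_is_unique():
    rng = np.random.default_rng(0)
    for L in rng.integers(-4, 5, size=(50, 3)):
        L = tuple(int(x) for x in L)
        if L == (0, 0, 0):
            continue
        mirror = tuple(-x for x in L)
        assert is_unique_pair(2, 2, L) != is_unique_pair(2, 2, mirror)


def test_cutoff_constant_bounds_erfc_tail():
    """5^(4/3) ensures the neglected tail stays ~1e-12 even if screening
    quintuples the polarizability (sigma ~ alpha^(1/3))."""
    assert UPSILON_CUTOFF == pytest.approx(5.0 ** (4.0 / 3.0))
    assert UPSILON_CUTOFF / 5.0 ** (1.0 / 3.0) == pytest.approx(5.0)
    assert erfc(5.0) < 2e-12
    assert erfc(5.0) == pytest.approx(1.5e-12, rel=0.05)
    assert math.exp(-25.0) == pytest.approx(1.4e-11, rel=0.05)


class TestRegionGrid:
    def test_single_isolated_atom_has_one_region_self_pair(self, isolated_atom):
        grid = build_region_grid(isolated_atom, 50.0)
        assert len(grid.occupied_regions) == 1
        assert len(grid.entries) == 1

    def test_region_volume_below_cutoff_sphere(self):
        s = make_crystal("rocksalt")
        for cutoff in (10.0, 25.0, 50.0):
            grid = build_region_grid(s, cutoff)
            vol = abs(np.linalg.det(grid.basis)) / np.prod(grid.counts)
            assert vol < 4.0 / 3.0 * math.pi * cutoff ** 3

    def test_periodic_self_images_match_brute_force(self):
        """One atom in a 40-bohr cube with a 50-bohr cutoff: only the six
        face-neighbor images (three unique ones) are inside the cutoff."""
        a = 40.0
        s = AtomicSystem(elements=("X",),
                         coordinates=np.array([[20.0, 20, 20]]),
                         lattice_vectors=a * np.eye(3),
                         periodic_flags=(True,) * 3,
                         r3_moments=np.array([12.0]))
        grid = build_region_grid(s, 50.0)
        lists = build_pair_lists(s, grid, np.array([10.0]), 50.0)
        _, blarge = brute_force_pairs(s, np.array([10.0]), 50.0)
        assert len(lists.large) == 1
        assert lists.large.n_images[0] == 3      # unique half of 6 faces
        assert np.allclose(lists.large.bare_sums[0], blarge[(0, 0)])

    def test_sixty_bohr_cube_has_no_image_within_fifty(self):
        s = AtomicSystem(elements=("X",),
                         coordinates=np.array([[30.0, 30, 30]]),
                         lattice_vectors=60.0 * np.eye(3),
                         periodic_flags=(True,) * 3,
                         r3_moments=np.array([12.0]))
        grid = build_region_grid(s, 50.0)
        # the region-pair catalog reaches into neighbor cells only
        assert all(max(abs(x) for x in L) <= 2 for _, _, L in grid.entries)
        lists = build_pair_lists(s, grid, np.array([10.0]), 50.0)
        assert len(lists.large) == 0

    def test_occupied_regions_independent_of_enormous_box_size(self):
        base = random_cluster(5, box=8.0, min_sep=2.5, seed=1)
        counts = []
        for scale in (1.0, 8.0):
            s = AtomicSystem(elements=base.elements,
                             coordinates=base.coordinates + 100.0 * scale,
                             lattice_vectors=scale * 300.0 * np.eye(3),
                             periodic_flags=(True,) * 3,
                             r3_moments=base.r3_moments)
            grid = build_region_grid(s, 20.0)
            counts.append(len(grid.occupied_regions))
        assert counts[0] == counts[1]


class TestPairListsVsBruteForce:
    @pytest.mark.parametrize("seed, box, pbc", [
        (3, 25.0, (True, True, True)),
        (4, 22.0, (True, True, False)),
        (5, 30.0, (False, False, False)),
    ])
    def test_lists_match_brute_force_enumeration(self, seed, box, pbc):
        s = random_cluster(40, box=box, min_sep=3.0, pbc=pbc, seed=seed)
        alphas = np.random.default_rng(seed).uniform(5.0, 40.0, 40)
        cutoff = 28.0
        grid = build_region_grid(s, cutoff)
        lists = build_pair_lists(s, grid, alphas, cutoff)
        bsmall, blarge = brute_force_pairs(s, alphas, cutoff)

        psmall = sorted(zip(lists.small.atom_a.tolist(),
                            lists.small.atom_b.tolist(),
                            *(lists.small.translation[:, k].tolist()
                              for k in range(3))))
        assert psmall == [t[:5] for t in bsmall]
        assert sorted(zip(lists.large.atom_a.tolist(),
                          lists.large.atom_b.tolist())) == sorted(blarge)
        for i, (a, b) in enumerate(zip(lists.large.atom_a,
                                       lists.large.atom_b)):
            assert np.allclose(lists.large.bare_sums[i], blarge[(a, b)],
                               atol=1e-14)

    def test_lists_invariant_to_region_granularity(self):
        s = random_cluster(25, box=24.0, min_sep=3.2,
                           pbc=(True, True, True), seed=7)
        alphas = np.random.default_rng(7).uniform(5.0, 40.0, 25)
        cutoff = 26.0
        ref = None
        for subdivide in (1, 2):
            grid = build_region_grid(s, cutoff, subdivide=subdivide)
            lists = build_pair_lists(s, grid, alphas, cutoff)
            key = sorted(zip(lists.small.atom_a.tolist(),
                             lists.small.atom_b.tolist(),
                             map(tuple, lists.small.translation.tolist())))
            if ref is None:
                ref = (key, len(lists.large))
            else:
                assert (key, len(lists.large)) == ref

    def test_nacl_worked_example_three_large_pairs(self):
        nacl = make_crystal("rocksalt")
        grid = build_region_grid(nacl, 50.0)
        lists = build_pair_lists(nacl, grid, np.array([30.0, 20.0]), 50.0)
        pairs = sorted(zip(lists.large.atom_a.tolist(),
                           lists.large.atom_b.tolist()))
        assert pairs == [(0, 0), (0, 1), (1, 1)]   # Na-Na, Na-Cl, Cl-Cl

    def test_isolated_atom_has_empty_lists(self, isolated_atom):
        grid = build_region_grid(isolated_atom, 50.0)
        lists = build_pair_lists(isolated_atom, grid, np.array([12.0]), 50.0)
        assert len(lists.small) == 0 and len(lists.large) == 0

    def test_large_list_bound_and_trace_identity(self):
        s = random_cluster(15, box=15.0, min_sep=2.5,
                           pbc=(True, True, True), seed=9)
        alphas = np.full(15, 20.0)
        grid = build_region_grid(s, 20.0)
        lists = build_pair_lists(s, grid, alphas, 20.0)
        n = s.natoms
        assert len(lists.large) <= n * (n + 1) // 2
        # eta trace identity on every stored small record
        tr = lists.small.eta[:, 0] + lists.small.eta[:, 3] + lists.small.eta[:, 5]
        assert np.max(np.abs(tr)) < 1e-12

    def test_coincident_nuclei_raise_geometry_error(self):
        s = AtomicSystem(elements=("C", "C"),
                         coordinates=np.zeros((2, 3)),
                         lattice_vectors=np.zeros((3, 3)),
                         periodic_flags=(False,) * 3,
                         r3_moments=np.array([14.0, 14.0]))
        grid = build_region_grid(s, 50.0)
        with pytest.raises(GeometryError, match="coincident"):
            build_pair_lists(s, grid, np.array([10.0, 10.0]), 50.0)


def test_region_pair_count_scales_linearly_on_replicated_supercells():
    """Replicating a cell along one axis grows the interacting
    region-pair-image count linearly (within rounding of the fit)."""
    counts = []
    sizes = (1, 2, 3)
    for n in sizes:
        s = make_crystal("cubic_toy", repeat=(n, 1, 1), a=8.0, seed=0)
        grid = build_region_grid(s, 12.0)
        counts.append(len(grid.entries))
    slope1 = counts[1] - counts[0]
    slope2 = counts[2] - counts[1]
    assert slope2 <= slope1 * 1.5 + 2   # no superlinear blow-up
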