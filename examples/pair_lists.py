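"""Interacting-pair lists for a periodic crystal.

Builds the two pair catalogs for the rock-salt primitive cell: the 'large'
list has one record per translation-unique atom pair with any image inside
the 50-bohr dipole cutoff (the bare dipole tensor pre-summed over all such
images), and the 'small' list one record per image whose Gaussian dipole
densities overlap (d <= 5^(4/3) sigma_AB), the only records that ever need
the erf-damped kernel.
"""

import numpy as np

from aimpol.fixtures import make_crystal
from aimpol.pairs import UPSILON_CUTOFF, build_pair_lists, build_region_grid

nacl = make_crystal("rocksalt", seed=1)
cutoff = 50.0
alphas = np.array([30.0, 20.0])      # static unscreened alphas, a.u.

grid = build_region_grid(nacl, cutoff)
lists = build_pair_lists(nacl, grid, alphas, cutoff)

labels = {0: "Na", 1: "Cl"}
print(f"overlap criterion: d <= 5^(4/3) sigma_AB = {UPSILON_CUTOFF:.4f} "
      "sigma_AB")
print(f"\nlarge list ({len(lists.large)} unique pairs, cutoff "
      f"{cutoff:.0f} bohr):")
for i in range(len(lists.large)):
    a, b = lists.large.atom_a[i], lists.large.atom_b[i]
    print(f"  {labels[a]}-{labels[b]}: {lists.large.n_images[i]} images "
          "pre-summed into one bare-tensor record")
print(f"\nsmall list: {len(lists.small)} overlapping image records")
d0 = lists.small.d.min()
print(f"closest pair distance: {d0:.3f} bohr")
print("\nonly three pair records cover the infinite crystal: every image")
print("sum is done once, here, and never repeated downstream.")
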