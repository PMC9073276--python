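"""Atomic systems, run configuration, and extended-xyz I/O.

An :class:`AtomicSystem` bundles the geometry (bohr internally), up to three
lattice vectors with periodicity flags, and the per-atom atom-in-material
(AIM) <r^3> radial moments that drive the Tkatchenko-Scheffler scaling law.

The extended-xyz dialect is:

* line 1: number of atoms,
* line 2: free-form header, optionally containing
  ``Lattice="ax ay az bx by bz cx cy cz"`` (angstrom) and ``pbc="T T F"``,
* body rows: ``element x y z r3moment`` with coordinates in angstrom and the
  <r^3> moment in atomic units.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields, replace

import numpy as np

from .errors import GeometryError, InputError
from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM

__all__ = [
    "AtomicSystem",
    "RunConfig",
    "read_system",
    "write_system",
    "read_config",
    "enclosing_parallelepiped",
]


@dataclass(frozen=True)
class AtomicSystem:
    """Geometry, periodicity and AIM input moments, all in atomic units."""

    elements: tuple[str, ...]
    coordinates: np.ndarray          # (natoms, 3), bohr
    lattice_vectors: np.ndarray      # (3, 3) rows, bohr; zero rows where aperiodic
    periodic_flags: tuple[bool, bool, bool]
    r3_moments: np.ndarray           # (natoms,), a.u.

    def __post_init__(self):
        coords = np.ascontiguousarray(self.coordinates, dtype=float)
        lat = np.ascontiguousarray(self.lattice_vectors, dtype=float)
        r3 = np.ascontiguousarray(self.r3_moments, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "lattice_vectors", lat)
        object.__setattr__(self, "r3_moments", r3)
        n = len(self.elements)
        if n < 1:
            raise InputError("a system needs at least one atom")
        if coords.shape != (n, 3) or r3.shape != (n,):
            raise InputError("per-atom fields must all have length natoms")
        if lat.shape != (3, 3):
            raise InputError("lattice_vectors must be 3x3")
        if np.any(r3 <= 0.0):
            raise InputError("all <r^3> moments must be > 0")
        if any(self.periodic_flags):
            vecs = lat[list(self.periodic_flags)]
            if np.any(np.linalg.norm(vecs, axis=1) == 0.0):
                raise GeometryError("periodic direction without a lattice vector")
        if all(self.periodic_flags) and abs(np.linalg.det(lat)) < 1e-12:
            raise GeometryError("zero-volume periodic cell")

    @property
    def natoms(self) -> int:
        return len(self.elements)

    def translated(self, shift) -> "AtomicSystem":
        """Rigidly translate all coordinates by ``shift`` (bohr)."""
        return replace(self, coordinates=self.coordinates + np.asarray(shift, float))


# Defaults below follow the published method: 50 bohr dipole interaction cutoff,
# Romberg order G = 4 (16 imaginary-frequency points), conditioned-residual
# convergence threshold 1e-5, Num_lookup = 1e5 with the itemized/lookup dispatch
# threshold at 2*Num_lookup, and (5, 7) Richardson extrapolation steps for the
# non-directional/fluctuating and static screenings respectively.
@dataclass(frozen=True)
class RunConfig:
    dipole_cutoff: float = 50.0        # bohr
    romberg_order: int = 4             # G; Nimfreqs = 2**G
    fcr_tol: float = 1e-5              # max |conditioned residual component|
    mz_length_tol: float | None = None  # default 1e-10 * ||W|| at solve time
    max_cr_steps: int = 1000
    num_lookup: int = 100_000
    threshold_wp_lookup: int = 200_000
    res_nondir: int = 5                # Richardson extrapolation steps
    res_static: int = 7
    ignore_pbc: bool = False
    use_direct_inversion: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.romberg_order <= 5):
            raise InputError("romberg_order must be in 1..5")
        if self.dipole_cutoff <= 0:
            raise InputError("dipole_cutoff must be positive")


_BOOL = {"true": True, "t": True, "1": True, "yes": True,
         "false": False, "f": False, "0": False, "no": False}


def read_config(path) -> RunConfig:
    """Parse a ``calculation_parameters.txt`` style key = value file.

    One ``key = value`` per line, ``#`` starts a comment, unknown keys are
    rejected so typos fail loudly.
    """
    known = {f.name: f for f in fields(RunConfig)}
    values = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in known:
                raise InputError(f"{path}:{lineno}: unknown parameter {key!r}")
            typ = known[key].type
            if typ in ("bool", bool):
                if val.lower() not in _BOOL:
                    raise InputError(f"{path}:{lineno}: bad boolean {val!r}")
                values[key] = _BOOL[val.lower()]
            elif typ in ("int", int):
                values[key] = int(float(val))
            else:
                values[key] = None if val.lower() == "none" else float(val)
    return RunConfig(**values)


_LATTICE_RE = re.compile(r'Lattice\s*=\s*"([^"]+)"')
_PBC_RE = re.compile(r'pbc\s*=\s*"([^"]+)"')


def read_system(xyz_path, config: RunConfig | None = None) -> AtomicSystem:
    """Read an extended-xyz file (angstrom) into an AtomicSystem (bohr).

    When ``config.ignore_pbc`` is set, all periodic flags are forced off,
    which turns off every interaction between periodic images.
    """
    config = config or RunConfig()
    with open(xyz_path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise InputError(f"{xyz_path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise InputError(f"{xyz_path}: first line must be the atom count")
    if len(lines) < 2 + natoms:
        raise InputError(f"{xyz_path}: truncated file")
    header = lines[1]

    lattice = np.zeros((3, 3))
    pbc = (False, False, False)
    m = _LATTICE_RE.search(header)
    if m:
        cell = np.array([float(x) for x in m.group(1).split()])
        if cell.size != 9:
            raise InputError(f"{xyz_path}: Lattice needs 9 numbers")
        lattice = cell.reshape(3, 3) * BOHR_PER_ANGSTROM
        pbc = (True, True, True)
    m = _PBC_RE.search(header)
    if m:
        toks = m.group(1).split()
        if len(toks) != 3:
            raise InputError(f"{xyz_path}: pbc needs 3 flags")
        pbc = tuple(t.upper().startswith("T") for t in toks)

    elements, coords, moments = [], [], []
    for i in range(natoms):
        toks = lines[2 + i].split()
        if len(toks) < 5:
            raise InputError(
                f"{xyz_path}: row {i + 1} lacks the <r^3> moment column "
                "(need: element x y z r3moment)")
        elements.append(toks[0])
        coords.append([float(t) for t in toks[1:4]])
        moments.append(float(toks[4]))

    if config.ignore_pbc:
        pbc = (False, False, False)
    lattice = lattice.copy()
    for k, flag in enumerate(pbc):
        if not flag:
            lattice[k] = 0.0
    if any(pbc):
        sub = lattice[list(pbc)]
        gram = sub @ sub.T
        if abs(np.linalg.det(gram)) < 1e-12:
            raise GeometryError(f"{xyz_path}: zero-volume periodic cell")

    return AtomicSystem(
        elements=tuple(elements),
        coordinates=np.asarray(coords) * BOHR_PER_ANGSTROM,
        lattice_vectors=lattice,
        periodic_flags=pbc,
        r3_moments=np.asarray(moments),
    )


def write_system(system: AtomicSystem, xyz_path, comment: str = "") -> None:
    """Write an AtomicSystem back to the extended-xyz dialect (angstrom)."""
    parts = []
    if any(system.periodic_flags):
        cell = system.lattice_vectors * ANGSTROM_PER_BOHR
        parts.append('Lattice="' + " ".join(f"{x:.12f}" for x in cell.ravel()) + '"')
    parts.append('pbc="' + " ".join("T" if f else "F" for f in system.periodic_flags) + '"')
    if comment:
        parts.append(comment)
    with open(xyz_path, "w") as fh:
        fh.write(f"{system.natoms}\n")
        fh.write(" ".join(parts) + "\n")
        coords = system.coordinates * ANGSTROM_PER_BOHR
        for el, xyz, r3 in zip(system.elements, coords, system.r3_moments):
            fh.write(f"{el} {xyz[0]:.12f} {xyz[1]:.12f} {xyz[2]:.12f} "
                     f"{float(r3)!r}\n")


def enclosing_parallelepiped(system: AtomicSystem,
                             padding: float | None = None) -> np.ndarray:
    """Basis vectors (rows) of a non-zero-volume box enclosing the unit cell.

    Periodic directions keep their lattice vectors (possibly non-orthogonal,
    e.g. triclinic).  Each non-periodic direction gets a vector perpendicular
    to the other two basis vectors, long enough to span every nucleus plus a
    padding (one dipole cutoff length by default) so that region membership
    tests near the boundary are always well defined.  The returned basis is
    anchored so that fractional coordinates of all nuclei lie in [0, 1).
    """
    if padding is None:
        padding = RunConfig().dipole_cutoff
    lat = system.lattice_vectors
    pbc = system.periodic_flags
    basis = np.zeros((3, 3))
    for k in range(3):
        if pbc[k]:
            basis[k] = lat[k]

    # Directions for the aperiodic axes: perpendicular to every periodic vector.
    nper = sum(pbc)
    free = [k for k in range(3) if not pbc[k]]
    if nper == 3:
        dirs = {}
    elif nper == 2:
        a, b = basis[[i for i in range(3) if pbc[i]]]
        n = np.cross(a, b)
        if np.linalg.norm(n) < 1e-12:
            raise GeometryError("collinear periodic lattice vectors")
        dirs = {free[0]: n / np.linalg.norm(n)}
    elif nper == 1:
        a = basis[[i for i in range(3) if pbc[i]][0]]
        if np.linalg.norm(a) < 1e-12:
            raise GeometryError("degenerate lattice vector")
        trial = np.eye(3)[np.argmin(np.abs(a))]
        u = np.cross(a, trial)
        u /= np.linalg.norm(u)
        v = np.cross(a, u)
        v /= np.linalg.norm(v)
        dirs = {free[0]: u, free[1]: v}
    else:
        dirs = {free[0]: np.array([1.0, 0, 0]),
                free[1]: np.array([0, 1.0, 0]),
                free[2]: np.array([0, 0, 1.0])}

    for k, u in dirs.items():
        proj = system.coordinates @ u
        length = (proj.max() - proj.min()) + 2.0 * padding
        basis[k] = u * length

    if abs(np.linalg.det(basis)) < 1e-12:
        raise GeometryError("degenerate (collinear) enclosing basis")
    return basis
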