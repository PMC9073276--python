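"""The TS-SCS pipeline: Tkatchenko-Scheffler scaling of free-atom references,
self-consistent screening solved per Cartesian direction per imaginary
frequency with the fail-proof conjugate residual solver, and Casimir-Polder
integration to per-atom C6 coefficients.

The four stages are: (a) TS scaling of free-atom (alpha, C6) by the AIM
<r^3> moment ratio, (b) construction of the small/large interacting-pair
lists from the static attenuation lengths, (c) for every grid point u and
every field direction, an FCR solve of the screening equations
mu_A/alpha_A(u) + sum_b tau^{Ab} mu_b = E0 (conditioned by
C = diag(sqrt(alpha_A(u)))), whose solutions assemble the per-atom screened
3x3 tensors, and (d) Casimir-Polder integration of the isotropic dynamic
polarizabilities to C6, plus unit-cell totals.
"""

from __future__ import annotations

import csv
import functools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from . import c6total
from .dipole import DipoleOperator
from .errors import ConvergenceError, InputError
from .fcr import fcr_solve
from .freqgrid import FrequencyGrid, build_grid, casimir_polder_c6, pade_alpha
from .pairs import PairLists, build_pair_lists, build_region_grid
from .system import AtomicSystem, RunConfig

__all__ = ["load_reference", "ts_scale", "UnscreenedSet", "unscreened_set",
           "solve_screened_tensors", "run_tsscs", "TsscsResult",
           "write_atom_csv", "write_summary"]

_DATA = Path(__file__).parent / "data" / "free_atom_reference.csv"


@functools.lru_cache(maxsize=4)
def _load_reference_cached(path_str: str):
    table = {}
    with open(path_str) as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        for row in reader:
            table[row["element"]] = (float(row["alpha_free"]),
                                     float(row["c6_free"]),
                                     float(row["r3_free"]))
    return table


def load_reference(path=None) -> dict:
    """Free-atom reference table: element -> (alpha_free, C6_free, r3_free)."""
    return dict(_load_reference_cached(str(path or _DATA)))


@dataclass(frozen=True)
class UnscreenedAtom:
    alpha0: float      # static unscreened polarizability, a.u.
    c6: float          # unscreened C6, a.u.
    wp: float          # characteristic one-pole frequency, a.u.


def ts_scale(element: str, r3_aim: float, reference: dict) -> UnscreenedAtom:
    """TS scaling law: alpha scales linearly and C6 quadratically with the
    AIM-to-free <r^3> moment ratio; wp = 4 C6 / (3 alpha^2) is invariant.
    """
    if element not in reference:
        raise InputError(f"element {element!r} not in the reference table")
    if r3_aim <= 0:
        raise InputError("r3_aim must be positive")
    alpha_free, c6_free, r3_free = reference[element]
    ratio = r3_aim / r3_free
    alpha0 = alpha_free * ratio
    c6 = c6_free * ratio * ratio
    return UnscreenedAtom(alpha0=alpha0, c6=c6,
                          wp=float(c6total.wp_from_c6(alpha0, c6)))


@dataclass
class UnscreenedSet:
    """Per-atom unscreened state on the frequency grid."""

    alpha0: np.ndarray        # (n,)
    c6: np.ndarray            # (n,)
    wp: np.ndarray            # (n,)
    alpha_u: np.ndarray       # (n, nimfreqs), one-pole dynamic values


def unscreened_set(system: AtomicSystem, grid: FrequencyGrid,
                   reference: dict | None = None) -> UnscreenedSet:
    reference = reference or load_reference()
    atoms = [ts_scale(el, r3, reference)
             for el, r3 in zip(system.elements, system.r3_moments)]
    alpha0 = np.array([a.alpha0 for a in atoms])
    c6 = np.array([a.c6 for a in atoms])
    wp = np.array([a.wp for a in atoms])
    alpha_u = pade_alpha(alpha0[:, None], wp[:, None], grid.omega_of_u[None, :])
    return UnscreenedSet(alpha0=alpha0, c6=c6, wp=wp, alpha_u=alpha_u)


def solve_screened_tensors(lists: PairLists, alpha_u: np.ndarray,
                           config: RunConfig, label: str = ""):
    """Screened per-atom 3x3 tensors at one frequency point.

    Three solves with a unit field along x, y, z replicated on every atom;
    the induced dipole of atom A under the unit field along t is column t of
    A's screened tensor.  Returns ``(tensors, info)`` where info carries the
    FCR iteration/matvec bookkeeping.
    """
    alpha_u = np.asarray(alpha_u, dtype=float)
    natoms = len(alpha_u)
    op = DipoleOperator(lists=lists, alphas=alpha_u, natoms=natoms)
    sqrt_a = np.sqrt(alpha_u)
    tensors = np.empty((natoms, 3, 3))
    info = {"iterations": [], "matvecs": [], "histories": []}

    dense_m = op.to_dense() if config.use_direct_inversion else None

    for t in range(3):
        e0 = np.zeros((natoms, 3))
        e0[:, t] = 1.0
        w = (sqrt_a[:, None] * e0).ravel()
        if dense_m is not None:
            y = scipy.linalg.solve(dense_m, w, assume_a="sym")
            iters, mv = 0, 0
            hist = []
        else:
            res = fcr_solve(op.matvec, w, tol=config.fcr_tol,
                            mz_tol=config.mz_length_tol,
                            max_iters=config.max_cr_steps)
            if res.status != "consistent":
                raise ConvergenceError(
                    f"FCR did not converge (status {res.status}) for field "
                    f"direction {'xyz'[t]}{' at ' + label if label else ''}")
            y = res.y
            iters, mv, hist = res.iterations, res.matvec_count, \
                res.residual_history
        mu = (sqrt_a * y.reshape(natoms, 3).T).T   # back-transform C^H y
        tensors[:, :, t] = mu
        info["iterations"].append(iters)
        info["matvecs"].append(mv)
        info["histories"].append(hist)
    return tensors, info


@dataclass
class TsscsResult:
    system: AtomicSystem
    config: RunConfig
    grid: FrequencyGrid
    unscreened: UnscreenedSet
    alpha_iso_u: np.ndarray          # (n, nimfreqs)
    alpha_static_tensor: np.ndarray  # (n, 3, 3)
    c6_atom: np.ndarray              # (n,)
    fcr_iterations_max: int          # max over the 3 * nimfreqs solves
    fcr_iterations_total: int        # summed over all solves
    matvecs_total: int

    @property
    def alpha_static_iso(self) -> np.ndarray:
        return np.trace(self.alpha_static_tensor, axis1=1, axis2=2) / 3.0

    @property
    def cell_tensor(self) -> np.ndarray:
        return self.alpha_static_tensor.sum(axis=0)

    @property
    def wp_screened(self) -> np.ndarray:
        return c6total.wp_from_c6(self.alpha_static_iso, self.c6_atom)

    def c6_cell_total(self) -> tuple[float, str]:
        if self.system.natoms < 2:
            return 0.0, "itemized"
        return c6total.c6_total(self.alpha_static_iso, self.wp_screened,
                                num_lookup=self.config.num_lookup,
                                threshold_wp_lookup=self.config.threshold_wp_lookup)


def run_tsscs(system: AtomicSystem, config: RunConfig | None = None,
              reference: dict | None = None) -> TsscsResult:
    """Full TS-SCS analysis of one atomic system."""
    config = config or RunConfig()
    grid = build_grid(config.romberg_order)
    uns = unscreened_set(system, grid, reference)

    region = build_region_grid(system, config.dipole_cutoff)
    # The small list is built once from the static unscreened alphas
    # (u = Nimfreqs maps to zero frequency) and reused at every grid point.
    lists = build_pair_lists(system, region, uns.alpha_u[:, -1],
                             config.dipole_cutoff)

    n = system.natoms
    alpha_iso_u = np.empty((n, grid.nimfreqs))
    static_tensor = None
    it_max = 0
    it_total = 0
    mv_total = 0
    for ui in range(grid.nimfreqs):
        tensors, info = solve_screened_tensors(
            lists, uns.alpha_u[:, ui], config,
            label=f"u index {ui + 1}/{grid.nimfreqs}")
        alpha_iso_u[:, ui] = np.trace(tensors, axis1=1, axis2=2) / 3.0
        it_max = max(it_max, *info["iterations"])
        it_total += sum(info["iterations"])
        mv_total += sum(info["matvecs"])
        if ui == grid.nimfreqs - 1:   # u = 1 is zero frequency: static
            static_tensor = 0.5 * (tensors + tensors.transpose(0, 2, 1))

    c6_atom = casimir_polder_c6(alpha_iso_u, grid)
    return TsscsResult(system=system, config=config, grid=grid,
                       unscreened=uns, alpha_iso_u=alpha_iso_u,
                       alpha_static_tensor=static_tensor, c6_atom=c6_atom,
                       fcr_iterations_max=it_max,
                       fcr_iterations_total=it_total,
                       matvecs_total=mv_total)


def write_atom_csv(result: TsscsResult, path) -> None:
    """Per-atom results (1-based indices): isotropic static alpha, the six
    unique static tensor components, and C6."""
    t = result.alpha_static_tensor
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["atom", "element", "alpha_static_iso",
                     "a11", "a12", "a13", "a22", "a23", "a33", "c6"])
        for i in range(result.system.natoms):
            wr.writerow([i + 1, result.system.elements[i],
                         f"{result.alpha_static_iso[i]:.8f}",
                         *(f"{t[i, s, u]:.8f}" for s, u in
                           ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))),
                         f"{result.c6_atom[i]:.8f}"])


def write_summary(result: TsscsResult, path) -> None:
    total, method = result.c6_cell_total()
    cell = result.cell_tensor
    with open(path, "w") as fh:
        fh.write("TS-SCS run summary (atomic units)\n")
        fh.write(f"atoms: {result.system.natoms}\n")
        fh.write(f"imaginary-frequency points: {result.grid.nimfreqs}\n")
        fh.write(f"unit-cell static polarizability tensor trace/3: "
                 f"{np.trace(cell) / 3.0:.8f}\n")
        fh.write(f"sum of atomic C6: {result.c6_atom.sum():.8f}\n")
        fh.write(f"total C6 over unordered atom pairs ({method}): {total:.8f}\n")
        fh.write(f"FCR iterations to converge (max over solves): "
                 f"{result.fcr_iterations_max}\n")
        fh.write(f"total FCR iterations: {result.fcr_iterations_total}\n")
        fh.write(f"large matrix-vector multiplies: {result.matvecs_total}\n")
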