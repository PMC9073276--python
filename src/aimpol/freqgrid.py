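"""Imaginary-frequency grid, Romberg weights, and Casimir-Polder C6.

The Casimir-Polder integral C6_AA = (3/pi) * int_0^inf alpha(i w)^2 dw is
mapped onto the unit interval by u = 1/(1 + w) <=> w = (1 - u)/u, under
which dw = -du/u^2 and

    C6 = (3/pi) * int_0^1 alpha(w(u))^2 / u^2 du.

u = 0 corresponds to infinite imaginary frequency, where the one-pole (Pade)
polarizability falls off as 1/w^2 ~ u^2, so the transformed integrand
vanishes at u = 0 and that endpoint can be dropped.  The remaining
Nimfreqs = 2**G points u_i = i / 2**G carry Romberg weights of order (G, G),
obtained programmatically by Richardson-extrapolating the nested trapezoid
rules; the quadrature error scales like 2**(-G(2G+2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = ["FrequencyGrid", "build_grid", "pade_alpha", "casimir_polder_c6",
           "romberg_weights"]


def romberg_weights(g: int) -> np.ndarray:
    """Weights of the order-(G, G) Romberg rule on [0, 1] at nodes i/2**G.

    Returns all 2**G + 1 node weights (including the u = 0 endpoint); the
    full set integrates constants exactly (weights sum to 1).
    """
    if not (1 <= g <= 10):
        raise InputError("Romberg order must be a small positive integer")
    npts = 2 ** g + 1
    # rows of the tableau as weight vectors over the fine grid
    tableau = []
    for k in range(g + 1):
        h = 1.0 / 2 ** k
        wk = np.zeros(npts)
        stride = 2 ** (g - k)
        idx = np.arange(0, npts, stride)
        wk[idx] = h
        wk[idx[0]] = h / 2.0
        wk[idx[-1]] = h / 2.0
        tableau.append(wk)
    for j in range(1, g + 1):
        fac = 4.0 ** j
        tableau = [(fac * tableau[k + 1] - tableau[k]) / (fac - 1.0)
                   for k in range(len(tableau) - 1)]
    return tableau[0]


@dataclass(frozen=True)
class FrequencyGrid:
    """Nontrivial integration points u in (0, 1] and their Romberg weights."""

    g: int
    u_points: np.ndarray      # 2**G points: i / 2**G, i = 1..2**G
    weights: np.ndarray       # Romberg weights at those points
    omega_of_u: np.ndarray    # mapped imaginary frequencies (1 - u)/u

    @property
    def nimfreqs(self) -> int:
        return len(self.u_points)


def build_grid(g: int) -> FrequencyGrid:
    """Build the 2**G-point grid; the u = 0 endpoint is dropped because the
    transformed Casimir-Polder integrand is exactly zero there."""
    if not (1 <= g <= 5):
        raise InputError("Romberg order G must be in 1..5")
    full = romberg_weights(g)
    u = np.arange(1, 2 ** g + 1) / 2 ** g
    return FrequencyGrid(g=g, u_points=u, weights=full[1:],
                         omega_of_u=(1.0 - u) / u)


def pade_alpha(alpha0, wp, omega):
    """One-pole model alpha(i w) = alpha0 / (1 + (w / wp)^2)."""
    alpha0 = np.asarray(alpha0, dtype=float)
    wp = np.asarray(wp, dtype=float)
    if np.any(alpha0 < 0):
        raise InputError("alpha0 must be >= 0")
    if np.any(wp <= 0):
        raise InputError("wp must be > 0")
    omega = np.asarray(omega, dtype=float)
    return alpha0 / (1.0 + (omega / wp) ** 2)


def casimir_polder_c6(alpha_of_u, grid: FrequencyGrid):
    """Same-species C6 from alpha values on the grid points.

    ``alpha_of_u`` has one value per grid point along its last axis (so a
    (natoms, nimfreqs) array yields per-atom C6).  For the exact one-pole
    form the closed-form value is (3/4) alpha0^2 wp.
    """
    a = np.asarray(alpha_of_u, dtype=float)
    if a.shape[-1] != grid.nimfreqs:
        raise InputError("one alpha value per grid point is required")
    integrand = a * a / grid.u_points ** 2
    return (3.0 / np.pi) * integrand @ grid.weights
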