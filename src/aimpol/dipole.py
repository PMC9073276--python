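"""Gaussian-attenuated dipole-dipole interaction tensors and the matrix-free
conditioned TS-SCS operator.

Conventions
-----------
Each atom carries a spherical Gaussian dipole density of width
``sigma = (sqrt(2/pi) * alpha / 3)**(1/3)``; a pair is attenuated over
``sigma_AB = sqrt(sigma_A**2 + sigma_B**2)``.  The *field-type* tensor

    B_st(delta, sigma) = d^2/dr_s dr_t [ erf(d / sigma) / d ]

tends to the bare point-dipole tensor ``eta_st / d^3`` as ``sigma -> 0``,
where ``eta_st = 3 delta_s delta_t / d^2 - delta_st`` (symmetric, traceless).
The interaction coefficient entering the self-consistent screening
coefficients matrix is ``tau_dipole = -B`` (so two collinear atoms polarize
more along the bond than across it).  For a unit field along direction t the
screening system is

    mu_A,s / alpha_A + sum_b tau_st^{Ab} mu_b,t = E0_A,s

whose conditioned form (diagonal conditioner C = diag(sqrt(alpha_A))) has
identity diagonal blocks plus sqrt(alpha_A alpha_B)-scaled off-diagonal
blocks; its eigenvalues cluster near one for well-separated atoms.

Only pairs in the 'small' list (overlapping Gaussians) need the erf-damped
kernel.  Pairs in the 'large' list use the bare tensor, which is accurate to
better than erfc(5) ~ 1.5e-12 at the small-list boundary even if screening
quintuples the polarizabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .errors import InputError
from .pairs import PairLists

__all__ = [
    "sigma_from_alpha",
    "pair_sigma",
    "bare_eta",
    "eta6_to_matrix",
    "screened_dipole_tensor",
    "tensor_factors",
    "screened_from_eta",
    "bare_from_eta",
    "nondir_coupling",
    "DipoleOperator",
]

_TWO_OVER_SQRT_PI = 2.0 / math.sqrt(math.pi)

# (s, t) index pairs of the six unique components, in storage order
# 11, 12, 13, 22, 23, 33.
_SIX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def sigma_from_alpha(alpha):
    """Spherical Gaussian dipole width sigma = (sqrt(2/pi) * alpha / 3)**(1/3)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0):
        raise InputError("polarizability must be non-negative")
    return (math.sqrt(2.0 / math.pi) * alpha / 3.0) ** (1.0 / 3.0)


def pair_sigma(alpha_a, alpha_b):
    """Pair attenuation length sigma_AB = sqrt(sigma_A^2 + sigma_B^2)."""
    sa = sigma_from_alpha(alpha_a)
    sb = sigma_from_alpha(alpha_b)
    return np.sqrt(sa * sa + sb * sb)


def bare_eta(delta):
    """Six unique components (11,12,13,22,23,33) of eta = 3 dd^T/d^2 - I."""
    delta = np.asarray(delta, dtype=float)
    d2 = float(delta @ delta)
    if d2 <= 0.0:
        raise InputError("bare_eta needs a non-zero displacement")
    x, y, z = delta
    return np.array([
        3.0 * x * x / d2 - 1.0,
        3.0 * x * y / d2,
        3.0 * x * z / d2,
        3.0 * y * y / d2 - 1.0,
        3.0 * y * z / d2,
        3.0 * z * z / d2 - 1.0,
    ])


def eta6_to_matrix(eta6):
    """Expand (..., 6) unique components into (..., 3, 3) symmetric matrices."""
    eta6 = np.asarray(eta6, dtype=float)
    out = np.empty(eta6.shape[:-1] + (3, 3))
    for k, (s, t) in enumerate(_SIX):
        out[..., s, t] = eta6[..., k]
        out[..., t, s] = eta6[..., k]
    return out


def tensor_factors(upsilon):
    """Radial factors of the erf-damped tensor at scaled distance v = d/sigma.

    B = F1(v) * eta / d^3 + F2(v) * (eta + I) / (3 d^3), with
    F1 = erf(v) - (2v/sqrt(pi)) exp(-v^2) and F2 = -(4 v^3/sqrt(pi)) exp(-v^2).
    F1 -> 1 and F2 -> 0 as v -> inf recovers the bare tensor.
    """
    v = np.asarray(upsilon, dtype=float)
    finite = np.isfinite(v)
    vf = np.where(finite, v, 0.0)
    g = np.exp(-vf * vf)
    f1 = np.where(finite, erf(vf) - _TWO_OVER_SQRT_PI * vf * g, 1.0)
    f2 = np.where(finite, -2.0 * _TWO_OVER_SQRT_PI * vf ** 3 * g, 0.0)
    return f1, f2


def screened_from_eta(eta6, d, sigma):
    """Erf-damped field tensor(s) (..., 3, 3) from stored eta and distance."""
    d = np.asarray(d, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore"):
        v = np.where(sigma > 0.0, d / np.where(sigma > 0.0, sigma, 1.0), np.inf)
    f1, f2 = tensor_factors(v)
    eta = eta6_to_matrix(eta6)
    eye = np.eye(3)
    d3 = d[..., None, None] ** 3
    f1 = f1[..., None, None]
    f2 = f2[..., None, None]
    return f1 * eta / d3 + f2 * (eta + eye) / (3.0 * d3)


def bare_from_eta(eta6, d):
    """Bare point-dipole field tensor(s) eta / d^3 as (..., 3, 3)."""
    d = np.asarray(d, dtype=float)
    return eta6_to_matrix(eta6) / d[..., None, None] ** 3


def screened_dipole_tensor(delta, sigma_ab):
    """3x3 erf-damped dipole field tensor for one displacement.

    Symmetric in the spatial indices and even under delta -> -delta; reduces
    to the bare tensor for sigma_ab = 0.
    """
    delta = np.asarray(delta, dtype=float)
    d = float(np.linalg.norm(delta))
    if d <= 0.0:
        raise InputError("screened_dipole_tensor needs |delta| > 0")
    if sigma_ab < 0.0:
        raise InputError("sigma_ab must be >= 0")
    return screened_from_eta(bare_eta(delta), np.float64(d), np.float64(sigma_ab))


def nondir_coupling(d, upsilon):
    """Isotropic (non-directional) pair coupling tr(tau)/3.

    Equals (4 / (3 sqrt(pi))) v^3 exp(-v^2) / d^3 > 0; this is the default
    scalar contraction of the Gaussian-damped tensor used by the incremental
    screening engine.
    """
    v = np.asarray(upsilon, dtype=float)
    d = np.asarray(d, dtype=float)
    return 2.0 * _TWO_OVER_SQRT_PI / 3.0 * v ** 3 * np.exp(-v * v) / d ** 3


@dataclass
class DipoleOperator:
    """Matrix-free conditioned TS-SCS coefficients matrix at one frequency.

    The unconditioned system is A mu = E0 with
    A = diag(1/alpha_A) + tau blocks; conditioning by C = diag(sqrt(alpha_A))
    gives M = C A C with identity diagonal blocks (plus periodic self-image
    terms) and off-diagonal blocks sqrt(alpha_A alpha_B) tau_st^{AB} summed
    over stored images.  One application touches each stored pair once.
    """

    lists: PairLists
    alphas: np.ndarray        # per-atom alpha(u), a.u.
    natoms: int

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.alphas.shape != (self.natoms,):
            raise InputError("alphas must have length natoms")
        if np.any(self.alphas <= 0):
            raise InputError("alphas must be positive")
        self._prepare()

    @property
    def shape(self):
        n = 3 * self.natoms
        return (n, n)

    def _prepare(self):
        sm, lg = self.lists.small, self.lists.large
        al = self.alphas
        # Large list: bare image-summed blocks, frequency independent in the
        # kernel; tau = -B.  Self-pair accumulations already carry both mirror
        # images.
        self._lg_a = lg.atom_a
        self._lg_b = lg.atom_b
        self._lg_tau = -eta6_to_matrix(lg.bare_sums)
        self._lg_w = np.sqrt(al[lg.atom_a] * al[lg.atom_b])
        # Small list: erf-damping correction (screened - bare) per stored image.
        self._sm_a = sm.atom_a
        self._sm_b = sm.atom_b
        sigma = pair_sigma(al[sm.atom_a], al[sm.atom_b])
        corr = -(screened_from_eta(sm.eta, sm.d, sigma) - bare_from_eta(sm.eta, sm.d))
        self_pair = (sm.atom_a == sm.atom_b)
        corr[self_pair] *= 2.0  # mirror image not stored; eta is even in delta
        self._sm_tau = corr
        self._sm_w = np.sqrt(al[sm.atom_a] * al[sm.atom_b])
        self._sm_self = self_pair

    def matvec(self, x):
        """y = M x for the conditioned coefficients matrix."""
        x = np.asarray(x, dtype=float)
        if x.shape != (3 * self.natoms,):
            raise InputError("operator/vector dimension mismatch")
        xb = x.reshape(self.natoms, 3)
        yb = xb.copy()  # identity diagonal blocks
        for a_idx, b_idx, tau, w, self_mask in (
            (self._lg_a, self._lg_b, self._lg_tau, self._lg_w,
             self._lg_a == self._lg_b),
            (self._sm_a, self._sm_b, self._sm_tau, self._sm_w, self._sm_self),
        ):
            if len(a_idx) == 0:
                continue
            wt = w[:, None, None] * tau
            fwd = np.einsum("nst,nt->ns", wt, xb[b_idx])
            np.add.at(yb, a_idx, fwd)
            cross = ~self_mask
            if np.any(cross):
                bwd = np.einsum("nst,ns->nt", wt[cross], xb[a_idx[cross]])
                np.add.at(yb, b_idx[cross], bwd)
        return yb.ravel()

    __call__ = matvec

    def to_dense(self):
        """Assemble M densely (guarded; intended for oracle tests)."""
        n = 3 * self.natoms
        if self.natoms > 200:
            raise InputError("dense export is limited to natoms <= 200")
        cols = [self.matvec(col) for col in np.eye(n)]
        return np.column_stack(cols)

    def export_matrix_market(self, path):
        """Write the dense conditioned matrix in MatrixMarket format
        (small systems only; same guard as :meth:`to_dense`)."""
        import scipy.io

        scipy.io.mmwrite(str(path), self.to_dense(),
                         comment="conditioned screening coefficients matrix")
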