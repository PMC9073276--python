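"""Fail-proof conjugate residual (FCR) solver for Hermitian linear systems.

FCR solves M y = W for any Hermitian M — positive definite, indefinite, or
singular: it returns a (nearly) exact solution when the system is
consistent, and the least-squares minimizer of |W - M y|^2 otherwise.

Each iteration spends two search directions, p^(i) and q^(i).  Both are
generated from the running residual image M z and made conjugate (in the
<M.|M.> inner product) to the stored directions, so the conditioned residual
norm Gamma = <z|z> strictly decreases every iteration: the leading step
coefficient satisfies <M p^(i)|z^(i-1)> = <M z|M z> > 0 regardless of the
sign structure of M's spectrum, which is what plain Orthomin-style conjugate
gradients lack (they divide by <z|M z>, which can vanish for indefinite M).

Every search direction is an odd polynomial in M applied to W — the pair
(p^(i), q^(i)) extends the chain to M^(4i-1) W — so the method is exactly a
conjugate-residual iteration on the positive-semidefinite operator M^2.
Consequences:

* y never acquires components in kernel(M): singular-but-consistent systems
  are solved exactly with y orthogonal to the kernel, and inconsistent ones
  leave exactly the kernel part of W in the residual (detected through
  ||M z|| -> 0 while z stays finite);
* with Xi distinct eigenvalues represented in W, exact arithmetic converges
  in at most ceiling(Xi/2) iterations (12 distinct eigenvalues -> at most
  6), and never more than ceiling(Nrows/2).

Steady-state cost is exactly four operator applications per iteration: one
each to the assembled p^(i) and q^(i), and one each to M p^(i) and M q^(i);
the latter pair maintains M z by the recurrence
Mz^(i) = Mz^(i-1) - gamma M^2 p^(i) - tau M^2 q^(i) and provides the stored
M^2 images that let every conjugation coefficient be evaluated through the
Hermitian adjoint (<M d|M v> = <d|M^2 v>) without further applications.
Coefficients with vanishing denominators (all of the form <Mp|Mp> or
<Mq|Mq>) are set to zero, their correct limiting value.

By default directions are re-orthogonalized against the full stored set,
which preserves the finite-termination bounds in floating point; a sliding
window (``reorth_pairs``) reproduces the fixed-memory profile of the
short-recurrence form at some cost in round-off resistance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, NumericalError

__all__ = ["FCRResult", "condition_system", "fcr_solve"]


@dataclass
class FCRResult:
    y: np.ndarray
    status: str                      # consistent | inconsistent | max_iterations
    iterations: int
    matvec_count: int
    residual_history: list           # Gamma per iteration, starting at Gamma^(0)
    matvecs_per_iteration: list = field(default_factory=list)
    audit: dict | None = None

    @property
    def converged(self) -> bool:
        return self.status == "consistent"


def condition_system(a_op, b, x0=None, conditioner=None):
    """Transform A x = B into the conditioned system M y = W.

    M = C A C^H is automatically Hermitian for any non-singular C;
    W = C (B - A x0); the back-transform is x = C^H y + x0, so the
    conditioned initial guess is always y = 0.  ``conditioner`` may be None
    (identity), a 1-D array (a diagonal C), or a dense matrix.

    Returns ``(m_op, w, back)`` where ``back(y)`` recovers x.
    """
    b = np.asarray(b)
    x0 = np.zeros_like(b) if x0 is None else np.asarray(x0)
    a_call = a_op if callable(a_op) else (lambda v, _a=np.asarray(a_op): _a @ v)

    if conditioner is None:
        return a_call, b - a_call(x0), (lambda y: y + x0)
    c = np.asarray(conditioner)
    if c.ndim == 1:
        if np.any(c == 0):
            raise InputError("singular diagonal conditioner")
        ch = np.conj(c)
        return (lambda v: c * a_call(ch * v)), c * (b - a_call(x0)), \
            (lambda y: ch * y + x0)
    if np.linalg.matrix_rank(c) < c.shape[0]:
        raise InputError("singular conditioner")
    ch_mat = c.conj().T
    return (lambda v: c @ a_call(ch_mat @ v)), c @ (b - a_call(x0)), \
        (lambda y: ch_mat @ y + x0)


def _dot(v, w):
    """Conjugate-linear dot product <v|w>; plain Euclidean for real vectors."""
    return np.vdot(v, w)


def _safe_div(num, den):
    return num / den if den != 0.0 else num * 0.0


def fcr_solve(m_op, w, tol: float = 1e-5, mz_tol: float | None = None,
              max_iters: int = 1000, reorth_pairs: int | None = None,
              audit: bool = False) -> FCRResult:
    """Run FCR on the Hermitian system M y = W.

    Exit conditions, in order:

    1. every |z component| < ``tol``          -> status ``consistent``;
    2. ||M z|| < ``mz_tol``                   -> status ``inconsistent``
       (default mz_tol = 1e-10 * ||W||): the part of the residual that M can
       reach is exhausted, the rest lies in kernel(M);
    3. the iteration count reaches ``max_iters`` -> status ``max_iterations``.

    A small ``max_iters`` with tiny tolerances gives the
    fixed-iteration-count mode used in polarizable-force-field dynamics.
    ``audit=True`` records per-iteration orthogonality and recurrence
    diagnostics (costing extra, uncounted operator applications).
    """
    w = np.asarray(w)
    if not np.all(np.isfinite(w)):
        raise NumericalError("right-hand side contains non-finite values")
    m_call = m_op if callable(m_op) else (lambda v, _m=np.asarray(m_op): _m @ v)
    if mz_tol is None:
        mz_tol = 1e-10 * np.linalg.norm(w)

    nmv = [0]

    def matvec(v):
        nmv[0] += 1
        out = np.asarray(m_call(v))
        if not np.all(np.isfinite(out)):
            raise NumericalError("operator produced non-finite values "
                                 f"(matvec {nmv[0]})")
        return out

    y = np.zeros_like(w)
    z = w.astype(w.dtype, copy=True)
    gamma_hist = [float(np.real(_dot(z, z)))]
    mv_per_iter = []
    audit_rec = {"mz_recurrence_relerr": [], "mp_mq_orth": [],
                 "pp_prev_orth": [], "qq_prev_orth": []} if audit else None

    if np.max(np.abs(z)) < tol:
        return FCRResult(y, "consistent", 0, 0, gamma_hist, mv_per_iter,
                         audit_rec)

    mz = matvec(z)
    # stored direction triples (d, M d, M^2 d) and Gram norms <Md|Md>
    dirs: list[tuple] = []
    status = "max_iterations"
    it = 0

    def make_direction():
        """Assemble the next direction from M z, conjugate to stored ones.

        Returns (d, Md, <Md|Md>) without yet applying M to Md: the M^2
        image is only needed if the iteration continues, so it is computed
        lazily by the caller (keeping converged solves at the minimum
        operator-application count).
        """
        t = mz.copy()
        window = dirs if reorth_pairs is None else dirs[-2 * reorth_pairs:]
        for d_j, _md_j, m2d_j, n_j in window:
            # <M t|M d_j> = <t|M^2 d_j> by Hermiticity
            t = t - _safe_div(_dot(m2d_j, t), n_j) * d_j
        if not np.any(t):
            return None
        md = matvec(t)
        # round-off-resistant re-projection using the true operator images
        for d_j, md_j, _m2d_j, n_j in window:
            c = _safe_div(_dot(md_j, md), n_j)
            if c != 0.0:
                t = t - c * d_j
                md = md - c * md_j
        n = float(np.real(_dot(md, md)))
        if n == 0.0:
            return None
        return t, md, n

    def residual_exhausted():
        """True when the reachable part of the residual is gone.

        ||M z|| below mz_tol alone is ambiguous at tight tolerances: for a
        well-conditioned consistent system ||M z|| ~ ||z|| shrinks together
        with z.  Inconsistency additionally requires ||M z|| << ||z||, i.e.
        the remaining residual lies (numerically) in kernel(M).  M z is
        recomputed directly before declaring, to rule out recurrence drift.
        """
        nonlocal mz
        znorm = float(np.linalg.norm(z))
        if not (np.linalg.norm(mz) < mz_tol
                and np.linalg.norm(mz) <= 1e-3 * znorm):
            return False
        mz = matvec(z)
        return bool(np.linalg.norm(mz) < mz_tol
                    and np.linalg.norm(mz) <= 1e-3 * znorm)

    while it < max_iters:
        it += 1
        mv_start = nmv[0]

        if residual_exhausted():
            status = "inconsistent"
            it -= 1
            break

        pair = []
        done = False
        for _sub in range(2):   # the p^(i) then the q^(i) direction
            out = make_direction()
            if out is None:
                break
            d, md, n = out
            coeff = _safe_div(_dot(md, z), n)
            y = y + coeff * d
            z = z - coeff * md
            if np.max(np.abs(z)) < tol:
                done = True      # M^2 d is only needed to keep iterating
                pair.append((d, md, None, n))
                break
            m2d = matvec(md)
            mz = mz - coeff * m2d
            dirs.append((d, md, m2d, n))
            pair.append(dirs[-1])

        gamma_hist.append(float(np.real(_dot(z, z))))
        mv_per_iter.append(nmv[0] - mv_start)
        if audit and not done:
            direct = m_call(z)
            denom = np.linalg.norm(direct) or 1.0
            audit_rec["mz_recurrence_relerr"].append(
                float(np.linalg.norm(mz - direct) / denom))
            if len(pair) == 2:
                audit_rec["mp_mq_orth"].append(
                    float(abs(_dot(pair[0][1], pair[1][1]))))
            if len(dirs) >= 3 and len(pair) == 2:
                audit_rec["pp_prev_orth"].append(
                    float(abs(_dot(dirs[-4][1], pair[0][1]))))
                audit_rec["qq_prev_orth"].append(
                    float(abs(_dot(dirs[-3][1], pair[1][1]))))

        if done or np.max(np.abs(z)) < tol:
            status = "consistent"
            break
        if not pair:   # no usable direction left: residual is in kernel(M)
            status = "inconsistent"
            break

    return FCRResult(y, status, it, nmv[0], gamma_hist, mv_per_iter, audit_rec)
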