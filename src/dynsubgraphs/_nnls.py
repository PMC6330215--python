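"""Exact nonnegative least squares with many right-hand sides.

Solves ``min_{X >= 0} ||A X - B||_F^2`` column by column using block
principal pivoting on the normal equations (Kim & Park, 2011), with a
per-column active-set fallback for the rare columns on which pivoting
cycles.  Exact subproblem solutions are what make the alternating
factorization sweep monotone in its objective, so approximate solvers
(multiplicative updates, projected gradient) are not acceptable here.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize

__all__ = ["nnls_multiple", "kkt_violation"]


def _solve_passive(AtA: np.ndarray, AtB: np.ndarray, F: np.ndarray,
                   cols: np.ndarray, X: np.ndarray, Y: np.ndarray) -> None:
    """Recompute X (passive part) and Y (dual, active part) for ``cols``.

    Columns are grouped by identical passive-set pattern so each distinct
    k x k system is factorized once.
    """
    patterns, inverse = np.unique(F[:, cols].T, axis=0, return_inverse=True)
    for p_idx in range(patterns.shape[0]):
        f = patterns[p_idx]
        group = cols[inverse == p_idx]
        if not f.any():
            X[:, group] = 0.0
            Y[:, group] = -AtB[:, group]
            continue
        Aff = AtA[np.ix_(f, f)]
        rhs = AtB[np.ix_(f, group)]
        try:
            c, low = linalg.cho_factor(Aff)
            sol = linalg.cho_solve((c, low), rhs)
        except linalg.LinAlgError:
            sol = np.linalg.lstsq(Aff, rhs, rcond=None)[0]
        X[:, group] = 0.0
        X[np.ix_(f, group)] = sol
        g = ~f
        Y[:, group] = 0.0
        if g.any():
            Y[np.ix_(g, group)] = AtA[np.ix_(g, f)] @ sol - AtB[np.ix_(g, group)]


def nnls_multiple(A: np.ndarray, B: np.ndarray, *, tol: float = 1e-12,
                  max_outer: int | None = None) -> np.ndarray:
    """Solve ``min_{X>=0} ||A X - B||_F^2`` for each column of B.

    Parameters
    ----------
    A : (m, k) design matrix, assumed full column rank in the typical case;
        rank deficiency is handled through a least-squares fallback.
    B : (m, n) right-hand sides.

    Returns
    -------
    X : (k, n) nonnegative solution with each column satisfying the KKT
        conditions of its NNLS problem to within ``tol`` scale.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    m, k = A.shape
    n = B.shape[1]
    if max_outer is None:
        max_outer = 10 * (k + 5)

    AtA = A.T @ A
    AtB = A.T @ B
    scale = max(np.abs(AtB).max(), 1.0)
    feas_tol = tol * scale

    F = np.zeros((k, n), dtype=bool)          # passive (unconstrained) set
    X = np.zeros((k, n))
    Y = -AtB.copy()                           # gradient AtA X - AtB
    alpha = np.full(n, 3, dtype=int)
    beta = np.full(n, k + 1, dtype=int)

    for _ in range(max_outer):
        infeas = ((X < -feas_tol) & F) | ((Y < -feas_tol) & ~F)
        ninf = infeas.sum(axis=0)
        bad = np.flatnonzero(ninf > 0)
        if bad.size == 0:
            return np.maximum(X, 0.0)

        improved = bad[ninf[bad] < beta[bad]]
        beta[improved] = ninf[improved]
        alpha[improved] = 3
        rest = np.setdiff1d(bad, improved, assume_unique=True)
        can_retry = alpha[rest] >= 1
        retry = rest[can_retry]
        backup = rest[~can_retry]
        alpha[retry] -= 1

        # full exchange for well-behaved columns
        flip = np.union1d(improved, retry)
        if flip.size:
            F[:, flip] ^= infeas[:, flip]
        # Murty's single-variable rule guarantees finite termination
        for j in backup:
            r = np.flatnonzero(infeas[:, j]).max()
            F[r, j] = not F[r, j]

        _solve_passive(AtA, AtB, F, bad, X, Y)

    # fallback: classical active-set NNLS on the unresolved columns
    infeas = ((X < -feas_tol) & F) | ((Y < -feas_tol) & ~F)
    unresolved = np.flatnonzero(infeas.any(axis=0))
    X = np.maximum(X, 0.0)
    for j in unresolved:
        X[:, j] = optimize.nnls(A, B[:, j])[0]
    return X


def kkt_violation(A: np.ndarray, B: np.ndarray, X: np.ndarray) -> float:
    """Largest KKT violation of a candidate NNLS solution, in gradient units.

    For ``min_{X>=0} ||A X - B||_F^2`` the conditions are ``X >= 0``,
    ``G = AtA X - AtB >= 0``, and ``X * G = 0`` elementwise.  Returns the
    maximum of the three violations (0 for an exact solution).
    """
    AtA = A.T @ A
    G = AtA @ X - A.T @ B
    neg_x = max(0.0, float((-X).max(initial=0.0)))
    neg_g = max(0.0, float((-G).max(initial=0.0)))
    comp = float(np.abs(X * G).max(initial=0.0))
    denom = max(np.abs(A.T @ B).max(), 1.0)
    return max(neg_x, neg_g, comp / denom)
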