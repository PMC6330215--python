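"""Sparse nonnegative matrix factorization by alternating NNLS.

Factorizes a nonnegative cohort matrix ``X`` (edges x windows*subjects)
into a basis of subgraphs ``W`` (edges x k) and time-dependent expression
coefficients ``H`` (k x windows*subjects) under the penalized objective

    min_{W,H >= 0}  1/2 ||X - W H||_F^2 + eta ||W||_F^2
                    + beta * sum_j (sum_i H[i, j])^2

The ridge term on ``W`` bounds subgraph edge weights; the squared-L1
column penalty on ``H`` promotes sparse expression at each time window.
Both nonnegative subproblems are solved exactly (block principal
pivoting), which makes every alternating sweep weakly decrease the
objective.  Initialization is the deterministic NNDSVD, so a fit is fully
reproducible without any random state.

`SparseNMF` exposes the factorization in scikit-learn convention: samples
are (subject, window) connectivity vectors, features are edges, and
``components_`` holds the subgraphs.  The module-level functions work in
the edges-by-columns orientation used by the rest of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._nnls import kkt_violation, nnls_multiple

__all__ = [
    "SparseNMF",
    "NMFResult",
    "objective",
    "nndsvd_init",
    "fit_sparse_nmf",
    "select_hyperparameters",
    "project",
]


def objective(X: np.ndarray, W: np.ndarray, H: np.ndarray,
              eta: float, beta: float) -> float:
    """Penalized factorization objective (see module docstring)."""
    if (W < 0).any() or (H < 0).any():
        raise ValueError("W and H must be entrywise nonnegative")
    resid = X - W @ H
    col_l1 = H.sum(axis=0)
    return (0.5 * float(np.sum(resid * resid))
            + eta * float(np.sum(W * W))
            + beta * float(np.sum(col_l1 * col_l1)))


def nndsvd_init(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic SVD-based nonnegative initialization (NNDSVD).

    The leading component uses the absolute leading singular vectors; each
    further component keeps whichever sign section (positive or negative
    parts) of its singular-vector pair carries more mass, ties resolved to
    the positive section.  Components beyond the numerical rank are left
    zero with a warning.  Plain variant: zeros are kept, not mean-filled.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("X must be nonnegative")
    if k < 1 or k > min(X.shape):
        raise ValueError(f"k={k} must be in [1, min(X.shape)]")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    W0 = np.zeros((X.shape[0], k))
    H0 = np.zeros((k, X.shape[1]))
    if rank == 0:
        warnings.warn("X is numerically zero; NNDSVD init is all zeros")
        return W0, H0
    W0[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    H0[0, :] = np.sqrt(s[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        if j >= rank:
            warnings.warn(f"k={k} exceeds numerical rank {rank}; "
                          "trailing components zero-padded")
            break
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        m_pos, m_neg = n_up * n_vp, n_un * n_vn
        if m_pos >= m_neg:  # ties to positive
            if m_pos == 0:
                continue
            W0[:, j] = np.sqrt(s[j] * m_pos) * up / n_up
            H0[j, :] = np.sqrt(s[j] * m_pos) * vp / n_vp
        else:
            W0[:, j] = np.sqrt(s[j] * m_neg) * un / n_un
            H0[j, :] = np.sqrt(s[j] * m_neg) * vn / n_vn
    return W0, H0


@dataclass
class NMFResult:
    """Fitted factorization in edges-by-columns orientation."""

    W: np.ndarray                    # (E, k) subgraph basis
    H: np.ndarray                    # (k, n_cols) expression coefficients
    objective_trace: np.ndarray      # objective after init and each sweep
    converged: bool
    n_iter: int
    eta: float
    beta: float
    kkt: float = np.nan              # max KKT violation at exit
    config: dict = field(default_factory=dict)


def _update_H(X: np.ndarray, W: np.ndarray, beta: float) -> np.ndarray:
    k = W.shape[1]
    if beta > 0:
        A = np.vstack([W, np.sqrt(2.0 * beta) * np.ones((1, k))])
        B = np.vstack([X, np.zeros((1, X.shape[1]))])
    else:
        A, B = W, X
    return nnls_multiple(A, B)


def _update_W(X: np.ndarray, H: np.ndarray, eta: float) -> np.ndarray:
    k = H.shape[0]
    if eta > 0:
        A = np.vstack([H.T, np.sqrt(2.0 * eta) * np.eye(k)])
        B = np.vstack([X.T, np.zeros((k, X.shape[0]))])
    else:
        A, B = H.T, X.T
    return nnls_multiple(A, B).T


def _sort_by_expression(W: np.ndarray, H: np.ndarray):
    """Fixed reporting order: subgraphs sorted by descending H row-sum."""
    order = np.argsort(-H.sum(axis=1), kind="stable")
    return W[:, order], H[order, :], order


def fit_sparse_nmf(X: np.ndarray, k: int, beta: float = 1e-2,
                   eta: float | str = "auto", tol: float = 1e-6,
                   max_iter: int = 200, sort_components: bool = True) -> NMFResult:
    """Fit the penalized NMF by alternating exact NNLS (ANLS).

    ``eta="auto"`` uses the square of the maximal element of X.  Stops when
    the relative objective change over one full sweep falls below ``tol``.
    A final H update (given the final W) is always performed so that
    projecting the training data onto the fitted basis reproduces H.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if (X < 0).any():
        raise ValueError("X must be nonnegative")
    if beta < 0 or (eta != "auto" and eta < 0):
        raise ValueError("beta and eta must be nonnegative")
    eta_val = float(X.max()) ** 2 if eta == "auto" else float(eta)

    W, H = nndsvd_init(X, k)
    trace = [objective(X, W, H, eta_val, beta)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        W = _update_W(X, H, eta_val)
        H = _update_H(X, W, beta)
        trace.append(objective(X, W, H, eta_val, beta))
        prev, cur = trace[-2], trace[-1]
        # second clause: objective at numerical zero (exact factorization)
        if (abs(prev - cur) <= tol * abs(prev)
                or cur <= 1e-12 * max(trace[0], 1.0)):
            converged = True
            break
    # H is exact given the final W by construction of the sweep order.
    if beta > 0:
        A_h = np.vstack([W, np.sqrt(2.0 * beta) * np.ones((1, k))])
        B_h = np.vstack([X, np.zeros((1, X.shape[1]))])
    else:
        A_h, B_h = W, X
    kkt = kkt_violation(A_h, B_h, H)
    if sort_components:
        W, H, _ = _sort_by_expression(W, H)
    return NMFResult(W=W, H=H, objective_trace=np.asarray(trace),
                     converged=converged, n_iter=n_iter, eta=eta_val,
                     beta=beta, kkt=kkt,
                     config={"k": k, "beta": beta, "eta": eta,
                             "tol": tol, "max_iter": max_iter})


def project(C_new: np.ndarray, W: np.ndarray, beta: float = 1e-2) -> np.ndarray:
    """Expression coefficients of new data on a fixed subgraph basis.

    Solves the same augmented nonnegative least-squares problem used for
    the H update, with W held fixed; the ridge term on W plays no role.
    """
    C_new = np.asarray(C_new, dtype=float)
    if C_new.ndim == 1:
        C_new = C_new[:, None]
    if C_new.shape[0] != W.shape[0]:
        raise ValueError(
            f"row mismatch: data has {C_new.shape[0]} edges, basis has {W.shape[0]}")
    return _update_H(C_new, W, beta)


def _masked_holdout(X: np.ndarray, frac: float, rng: np.random.Generator):
    """Random entry mask plus the train matrix with held-out entries imputed
    by their column means (computed from the retained entries)."""
    mask = rng.random(X.shape) < frac
    X_train = X.copy()
    keep = ~mask
    with np.errstate(invalid="ignore"):
        col_sums = np.where(keep, X, 0.0).sum(axis=0)
        col_n = keep.sum(axis=0)
        col_means = np.where(col_n > 0, col_sums / np.maximum(col_n, 1),
                             X.mean())
    X_train[mask] = np.broadcast_to(col_means, X.shape)[mask]
    return mask, X_train


def select_hyperparameters(X: np.ndarray, k_grid, beta_grid,
                           method: str = "holdout", holdout_frac: float = 0.1,
                           seed: int | None = 0, tol: float = 1e-5,
                           max_iter: int = 100):
    """Choose (k, beta) on a grid.

    ``holdout`` (default): a random fraction of entries is hidden (replaced
    by column means during fitting) and the pair minimizing mean-squared
    error on the hidden entries wins.  ``elbow``: fit on the full matrix
    and pick the k of maximum discrete curvature of the training error
    curve (beta fixed at the middle of its grid).  Returns
    ``(k, beta, error_surface)`` with the surface as a records array of
    (k, beta, error).
    """
    k_grid = list(k_grid)
    beta_grid = list(beta_grid)
    if not k_grid or not beta_grid:
        raise ValueError("grids must be nonempty")
    if len(k_grid) == 1 and len(beta_grid) == 1:
        return k_grid[0], beta_grid[0], np.array(
            [(k_grid[0], beta_grid[0], np.nan)],
            dtype=[("k", int), ("beta", float), ("error", float)])

    records = []
    if method == "holdout":
        rng = np.random.default_rng(seed)
        mask, X_train = _masked_holdout(X, holdout_frac, rng)
        for k in k_grid:
            for beta in beta_grid:
                res = fit_sparse_nmf(X_train, k=k, beta=beta, tol=tol,
                                     max_iter=max_iter)
                err = float(np.mean(((X - res.W @ res.H)[mask]) ** 2))
                records.append((k, beta, err))
    elif method == "elbow":
        beta = beta_grid[len(beta_grid) // 2]
        errs = []
        for k in k_grid:
            res = fit_sparse_nmf(X, k=k, beta=beta, tol=tol, max_iter=max_iter)
            err = float(np.mean((X - res.W @ res.H) ** 2))
            errs.append(err)
            records.append((k, beta, err))
        if len(k_grid) >= 3:
            curv = np.diff(errs, 2)
            k_best = k_grid[int(np.argmax(curv)) + 1]
        else:
            k_best = k_grid[int(np.argmin(errs))]
        surface = np.array(records,
                           dtype=[("k", int), ("beta", float), ("error", float)])
        return k_best, beta, surface
    else:
        raise ValueError(f"unknown method {method!r}")

    surface = np.array(records,
                       dtype=[("k", int), ("beta", float), ("error", float)])
    best = surface[np.argmin(surface["error"])]
    return int(best["k"]), float(best["beta"]), surface


class SparseNMF(TransformerMixin, BaseEstimator):
    """Sparse NMF decomposition of window-wise connectivity vectors.

    Scikit-learn-style estimator.  Input ``X`` has one row per
    (subject, window) sample and one column per network edge; ``fit``
    learns nonnegative subgraphs (``components_``, shape
    ``(n_components, n_edges)``) and per-sample expression coefficients
    (``coefficients_``), and ``transform`` projects new connectivity
    vectors onto the learned subgraphs by the same exact nonnegative
    least-squares step.

    Parameters
    ----------
    n_components : number of subgraphs k.
    beta : squared-L1 sparsity penalty on each sample's coefficients.
    eta : ridge penalty on the subgraph basis; ``"auto"`` uses max(X)^2.
    tol : relative objective-change stopping threshold.
    max_iter : maximum number of alternating sweeps.
    sort_components : report subgraphs sorted by descending total
        expression (NMF is permutation-invariant; a fixed order makes
        outputs comparable across runs).

    Attributes
    ----------
    components_ : (n_components, n_features) nonnegative subgraph basis.
    coefficients_ : (n_samples, n_components) expression coefficients.
    objective_trace_ : objective value after init and after each sweep.
    converged_ : whether the tolerance was reached within max_iter.
    eta_ : resolved ridge penalty value.
    kkt_ : largest KKT violation of the final coefficient subproblem.
    """

    def __init__(self, n_components: int = 10, beta: float = 1e-2,
                 eta: float | str = "auto", tol: float = 1e-6,
                 max_iter: int = 200, sort_components: bool = True):
        self.n_components = n_components
        self.beta = beta
        self.eta = eta
        self.tol = tol
        self.max_iter = max_iter
        self.sort_components = sort_components

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        res = fit_sparse_nmf(X.T, k=self.n_components, beta=self.beta,
                             eta=self.eta, tol=self.tol,
                             max_iter=self.max_iter,
                             sort_components=self.sort_components)
        self.components_ = res.W.T
        self.coefficients_ = res.H.T
        self.objective_trace_ = res.objective_trace
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.eta_ = res.eta
        self.kkt_ = res.kkt
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        return project(X.T, self.components_.T, beta=self.beta).T

    def fit_transform(self, X, y=None):
        return self.fit(X).coefficients_

    def inverse_transform(self, coefficients):
        check_is_fitted(self, "components_")
        return np.asarray(coefficients) @ self.components_

    def reconstruction_error(self, X):
        """Relative Frobenius reconstruction error on fitted data."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        num = np.linalg.norm(X - self.coefficients_ @ self.components_)
        return float(num / max(np.linalg.norm(X), np.finfo(float).tiny))
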