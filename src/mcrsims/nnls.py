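"""Exact multi-right-hand-side non-negative least squares.

Solves  min_X ||A X - B||_F  subject to X >= 0 elementwise, given the
normal-equation cross-products AtA = A'A (k x k) and AtB = A'B (k x n).
Right-hand sides sharing an identical passive (unconstrained) variable set
are grouped so each distinct k' x k' system is factorized once — the
fast-combinatorial active-set strategy that makes constrained ALS on
hundreds of thousands of pixels practical.  An optional warm start (the
support of the previous half-step's solution) lets most columns verify
optimal in a single screened pass.  Columns that do not settle within the
iteration budget fall back to scipy's single-column NNLS, so every
returned column is an exact constrained minimizer.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

__all__ = ["nnls_multi"]


def _sym_solve(AtA: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve a (near-)PSD system, falling back to lstsq when singular.

    Ill-conditioned passive sets may yield inexact columns here; the outer
    optimality check routes those to the guaranteed solver, so no
    conditioning diagnostics are needed at this level.
    """
    try:
        return np.linalg.solve(AtA, rhs)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(AtA, rhs, rcond=None)[0]


def _solve_passive(AtA: np.ndarray, AtB: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Unconstrained normal-equation solve restricted to each column's passive set.

    Columns sharing a passive pattern (encoded as an integer bit mask) are
    grouped so each distinct subsystem is factorized once.
    """
    k, n = AtB.shape
    X = np.zeros((k, n))
    if n == 0:
        return X
    if P.all():
        return _sym_solve(AtA, AtB)
    if k <= 63:
        weights = np.left_shift(np.uint64(1), np.arange(k, dtype=np.uint64))
        codes = P.T.astype(np.uint64) @ weights
    else:  # rare: very high component counts fall back to byte patterns
        codes = np.packbits(P, axis=0).T.copy().view([("", np.uint8)] * ((k + 7) // 8)).ravel()
    uniq, inverse = np.unique(codes, return_inverse=True)
    inverse = np.asarray(inverse).ravel()
    order = np.argsort(inverse, kind="stable")
    bounds = np.searchsorted(inverse[order], np.arange(uniq.size + 1))
    for g in range(uniq.size):
        cols = order[bounds[g] : bounds[g + 1]]
        p = P[:, cols[0]]
        if not p.any():
            continue
        X[np.ix_(p, cols)] = _sym_solve(AtA[np.ix_(p, p)], AtB[np.ix_(p, cols)])
    return X


def _grad_thresholds(tol: float, X: np.ndarray) -> np.ndarray:
    """Per-column gradient tolerance, scaled with the solution magnitude."""
    return tol * (1.0 + np.abs(X).max(axis=0))


def _refine(
    AtA: np.ndarray, AtB: np.ndarray, P: np.ndarray, X: np.ndarray,
    tol: float, max_outer: int,
) -> np.ndarray:
    """Active-set refinement of the given columns; arrays are modified in place.

    Returns the indices of columns that failed to settle — because the
    iteration budget ran out, or because an ill-conditioned passive system
    left a non-zero gradient on the passive set (the solve cannot be
    trusted, and active-set moves will not repair it).
    """
    k, n = AtB.shape
    D = np.where(P, np.clip(X, 0.0, None), 0.0)  # last feasible iterate
    F = np.arange(n)
    giveup: list[np.ndarray] = []
    n_iter = 0
    while F.size:
        # Inner loop: step infeasible columns back to the feasibility boundary.
        H = F[(X[:, F] < -tol).any(axis=0)]
        while H.size:
            n_iter += 1
            if n_iter > max_outer:
                giveup.append(F)
                return np.concatenate(giveup)
            neg = P[:, H] & (X[:, H] < -tol)
            alpha = np.full((k, H.size), np.inf)
            ii, jj = np.nonzero(neg)
            denom = D[ii, H[jj]] - X[ii, H[jj]]
            alpha[ii, jj] = np.where(denom > 0, D[ii, H[jj]] / denom, 0.0)
            amin = alpha.min(axis=0)
            imin = alpha.argmin(axis=0)
            D[:, H] = D[:, H] - amin[None, :] * (D[:, H] - X[:, H])
            D[imin, H] = 0.0
            P[imin, H] = False
            X[:, H] = _solve_passive(AtA, AtB[:, H], P[:, H])
            H = H[(X[:, H] < -tol).any(axis=0)]
        X[:, F] = np.clip(X[:, F], 0.0, None)
        # Optimality needs BOTH: gradient <= 0 off the passive set, and
        # gradient ~ 0 on it (a solved system); a passive-gradient residual
        # beyond tolerance means the solve was inaccurate.
        W = AtB[:, F] - AtA @ X[:, F]
        thr = _grad_thresholds(tol, X[:, F])
        untrusted = (np.abs(np.where(P[:, F], W, 0.0)) > thr).any(axis=0)
        if untrusted.any():
            giveup.append(F[untrusted])
            F = F[~untrusted]
            if not F.size:
                break
            W = W[:, ~untrusted]
            thr = thr[~untrusted]
        W[P[:, F]] = -np.inf
        not_opt = (W > thr).any(axis=0)
        if not not_opt.any():
            break
        n_iter += 1
        if n_iter > max_outer:
            giveup.append(F[not_opt])
            break
        # Move each non-optimal column's most violating variable into the passive set.
        add = W[:, not_opt].argmax(axis=0)
        F = F[not_opt]
        P[add, F] = True
        D[:, F] = X[:, F]
        X[:, F] = _solve_passive(AtA, AtB[:, F], P[:, F])
    return np.concatenate(giveup) if giveup else np.empty(0, dtype=int)


def _fallback(AtA: np.ndarray, AtB: np.ndarray, cols: np.ndarray, X: np.ndarray) -> None:
    """Solve remaining columns with scipy's guaranteed NNLS.

    The quadratic is reduced through the eigendecomposition of AtA
    (numerically rank-revealing, so exactly singular Gram matrices — e.g.
    duplicated loading rows in an over-fitted model — are handled without
    regularization): with AtA = V diag(lam) V', minimizing
    x'AtA x - 2 (AtB_j)'x over x >= 0 equals NNLS on the reduced factor
    sqrt(lam) V' against sqrt(lam)^-1 V' AtB_j.
    """
    lam, V = np.linalg.eigh(AtA)
    keep = lam > max(lam[-1], 0.0) * 1e-13
    if not keep.any():
        X[:, cols] = 0.0
        return
    root = np.sqrt(lam[keep])
    Vk = V[:, keep]
    A_red = (Vk * root).T  # r x k, with A_red' A_red = AtA (numerically)
    for j in cols:
        b_red = (Vk.T @ AtB[:, j]) / root
        X[:, j], _ = _scipy_nnls(A_red, b_red)


def nnls_multi(
    AtA: np.ndarray,
    AtB: np.ndarray,
    max_outer: int | None = None,
    warm_start: np.ndarray | None = None,
) -> np.ndarray:
    """Columnwise non-negative least squares from cross-products.

    Parameters
    ----------
    AtA : (k, k) array
        Gram matrix of the fixed factor.
    AtB : (k, n) array
        Fixed factor times the data, one column per subproblem.
    max_outer : int, optional
        Active-set iteration budget before falling back to the single-column
        solver; default ``30 * k + 10``.
    warm_start : (k, n) bool array, optional
        Initial passive sets, e.g. the support of the previous ALS
        half-step's solution.  A good guess lets most columns verify
        optimal in one screened pass; a bad one only costs extra
        iterations — the result is an exact minimizer either way.

    Returns
    -------
    (k, n) array, elementwise >= 0, each column an exact minimizer of its
    constrained subproblem.
    """
    AtA = np.asarray(AtA, dtype=float)
    AtB = np.asarray(AtB, dtype=float)
    k, n = AtB.shape
    if AtA.shape != (k, k):
        raise ValueError("AtA must be (k, k) matching AtB's row count")
    if max_outer is None:
        max_outer = 30 * k + 10
    tol = 10 * np.finfo(float).eps * max(np.abs(AtA).sum(axis=0).max(), 1.0) * k

    if warm_start is None:
        # The unconstrained solution's positive part seeds the passive sets;
        # an elementwise-feasible column whose gradient verifies is optimal
        # as it stands (the gradient check also catches inaccurate solves of
        # an ill-conditioned Gram matrix).
        P = np.ones((k, n), dtype=bool)
        X = _solve_passive(AtA, AtB, P)
        W = AtB - AtA @ X
        accurate = (np.abs(W) <= _grad_thresholds(tol, X)).all(axis=0)
        P = X > 0
        X[~P] = 0.0
        bad = np.nonzero(~(P.all(axis=0) & accurate))[0]
    else:
        P = warm_start.copy()
        X = _solve_passive(AtA, AtB, P)
        # One screened pass: a column is done if feasible on its passive set,
        # solved accurately there (passive gradient ~ 0), and
        # gradient-optimal off it; only violators enter refinement.  The
        # screen uses the raw solve — clipping happens only after refinement,
        # else infeasible entries would masquerade as feasible.
        infeasible = ((X < -tol) & P).any(axis=0)
        W = AtB - AtA @ X
        thr = _grad_thresholds(tol, X)
        inaccurate = (np.abs(np.where(P, W, 0.0)) > thr).any(axis=0)
        W[P] = -np.inf
        bad = np.nonzero(infeasible | inaccurate | (W > thr).any(axis=0))[0]

    if bad.size:
        AtB_bad = AtB[:, bad].copy()
        Pb = P[:, bad]  # fancy indexing copies; _refine mutates freely
        if warm_start is None:
            Xb = _solve_passive(AtA, AtB_bad, Pb)  # re-solve on the seeded passive sets
        else:
            Xb = X[:, bad].copy()
        unresolved = _refine(AtA, AtB_bad, Pb, Xb, tol, max_outer)
        X[:, bad] = Xb
        if unresolved.size:
            _fallback(AtA, AtB, bad[unresolved], X)
    np.clip(X, 0.0, None, out=X)
    return X
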