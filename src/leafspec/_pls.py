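"""Minimal PLS1 (NIPALS) core for the tight inner loops of variable selection.

Selection algorithms evaluate tens of thousands of small cross-validated PLS
fits; this module keeps those fits to a few matrix products. The public
modeling API (`leafspec.modeling.fit_plsr`) uses scikit-learn instead, and the
two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def pls1_coefficients(X: np.ndarray, y: np.ndarray, ncomp: int,
                      ) -> tuple[np.ndarray, float]:
    """NIPALS PLS1 regression coefficients after mean-centering.

    Returns ``(coef, intercept)`` so that predictions are ``X @ coef +
    intercept``. ``ncomp`` is clipped to ``min(ncomp, p, n - 1)`` and to the
    rank actually reachable (deflation stops early on degenerate residuals).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    A = max(1, min(ncomp, p, n - 1))
    mx = X.mean(axis=0)
    my = y.mean()
    Xc = X - mx
    yc = y - my
    W = np.empty((p, A))
    P = np.empty((p, A))
    q = np.empty(A)
    a = 0
    for _ in range(A):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        if tt < _EPS:
            break
        pvec = Xc.T @ t / tt
        W[:, a] = w
        P[:, a] = pvec
        q[a] = (yc @ t) / tt
        Xc -= np.outer(t, pvec)
        yc -= q[a] * t
        a += 1
    if a == 0:
        return np.zeros(p), float(my)
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    coef = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
    return coef, float(my - mx @ coef)


def make_folds(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded shuffled fold assignment (values 0..folds-1, balanced sizes)."""
    if folds < 2 or folds > n:
        raise ValueError(f"need 2 <= folds <= n, got folds={folds}, n={n}")
    idx = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(idx, folds)):
        fold_id[chunk] = f
    return fold_id


def rmsecv(X: np.ndarray, y: np.ndarray, ncomp: int,
           fold_id: np.ndarray) -> float:
    """Root mean squared error of cross-validation for a fixed fold partition.

    Reusing one partition across candidate subsets makes RMSECV comparisons
    paired, which reduces selection variance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    sse = 0.0
    for f in np.unique(fold_id):
        test = fold_id == f
        train = ~test
        coef, icpt = pls1_coefficients(X[train], y[train], ncomp)
        resid = y[test] - (X[test] @ coef + icpt)
        sse += float(resid @ resid)
    return float(np.sqrt(sse / n))
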