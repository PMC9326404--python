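"""Characteristic-variable selection: CARS and random frog.

Both selectors score subsets of predictor columns (wavelengths or image
features) by the root mean squared error of 5-fold cross-validation (RMSECV)
of a PLS regression against leaf potassium content, and both are fully
seeded.

**CARS** (competitive adaptive reweighted sampling) runs a Monte Carlo loop
(default 50 runs): each run fits PLS on a random 80% row subset, ranks
variables by the absolute value of their regression coefficients, applies an
enforced exponentially decreasing retention schedule, then adaptively
resamples the retained variables with probability proportional to their
coefficient magnitudes. The subset with the lowest RMSECV across runs wins.

**Random frog** iterates (default 10,000 times) a reversible-jump-style
subset walk: a candidate subset is proposed by resizing the working subset
around its nominal size and swapping members, and is accepted if its RMSECV
improves, or otherwise with a small probability proportional to the RMSECV
ratio. Each variable's selection probability is the fraction of iterations
whose working subset contains it; variables at or above a stage-specific
probability threshold are selected (defaults 0.40 / 0.21 / 0.23 for the
budding / flowering / boll stages).

Selections are capped at 10 characteristic variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from math import ceil, log

import numpy as np

from ._pls import make_folds, pls1_coefficients, rmsecv

__all__ = [
    "SelectionResult",
    "SelectionError",
    "STAGE_RF_THRESHOLDS",
    "DEFAULT_CAP",
    "edf_ratio",
    "cars_select",
    "random_frog_select",
    "cap_selection",
]

DEFAULT_CAP = 10

#: Per-stage random-frog selection-probability thresholds.
STAGE_RF_THRESHOLDS: dict[str, float] = {
    "budding": 0.40,
    "flowering": 0.21,
    "boll": 0.23,
}


class SelectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selection run.

    ``scores`` is per-variable: |PLS coefficient| of winning-subset members
    for CARS (zero elsewhere), selection probability in [0, 1] for random
    frog. ``selected_indices`` are unique and ascending; ranking is recovered
    from ``scores``.
    """

    method: str  # "CARS" or "RF"
    selected_indices: np.ndarray
    scores: np.ndarray
    rmsecv_best: float
    seed: int
    rmsecv_trajectory: np.ndarray | None = None  # per-run RMSECV (CARS)

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected_indices, dtype=int)
        if sel.size != np.unique(sel).size or np.any(np.diff(sel) < 0):
            raise ValueError("selected indices must be unique and sorted")
        object.__setattr__(self, "selected_indices", sel)

    def ranked_indices(self) -> np.ndarray:
        """Selected indices in descending score order (ties: lower index)."""
        sel = self.selected_indices
        order = np.lexsort((sel, -self.scores[sel]))
        return sel[order]


def edf_ratio(iteration: int, n_runs: int, n_vars: int) -> float:
    """Exponentially decreasing retention fraction of the CARS schedule.

    ``r_i = a * exp(-k * i)`` with boundary constraints ``r_1 = 1`` and
    ``r_N = 2 / p``, i.e. ``a = (p/2)^(1/(N-1))``, ``k = ln(p/2)/(N-1)``.
    """
    if n_vars < 3:
        raise SelectionError(f"CARS schedule undefined for p={n_vars} < 3")
    if n_runs < 2:
        raise SelectionError("CARS needs at least 2 Monte Carlo runs")
    if not 1 <= iteration <= n_runs:
        raise ValueError(f"iteration must lie in 1..{n_runs}")
    a = (n_vars / 2.0) ** (1.0 / (n_runs - 1))
    k = log(n_vars / 2.0) / (n_runs - 1)
    return float(a * np.exp(-k * iteration))


def _check_xy(X: np.ndarray, y: np.ndarray, folds: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (samples, variables), y (samples,)")
    if X.shape[0] < folds:
        raise SelectionError(f"need at least {folds} samples for {folds}-fold CV")
    if X.shape[1] < 3:
        raise SelectionError("need at least 3 candidate variables")
    if np.ptp(y) <= 0 or y.std() <= 0:
        raise SelectionError("response has zero variance")
    return X, y


def _inner_ncomp(n_subset: int, n_samples: int, folds: int) -> int:
    # latent count used for every subset evaluation inside selection loops
    return max(1, min(10, n_subset, n_samples - ceil(n_samples / folds) - 1))


def _rank_by_weight(indices: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Indices ordered by descending weight, ties broken by lower index."""
    order = np.lexsort((indices, -weights))
    return indices[order]


def cars_select(X: np.ndarray, y: np.ndarray, n_runs: int = 50,
                folds: int = 5, seed: int = 0, subsample: float = 0.8,
                cap: int | None = DEFAULT_CAP) -> SelectionResult:
    """Competitive adaptive reweighted sampling over the columns of X."""
    X, y = _check_xy(X, y, folds)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    fold_id = make_folds(n, folds, rng)
    n_sub = max(folds, ceil(subsample * n))

    subset = np.arange(p)
    best_rmse = np.inf
    best_subset = subset
    best_weights = np.ones(p)
    trajectory = np.empty(n_runs)

    for run in range(1, n_runs + 1):
        rows = rng.choice(n, size=n_sub, replace=False)
        ncomp = _inner_ncomp(subset.size, n, folds)
        coef, _ = pls1_coefficients(X[np.ix_(rows, subset)], y[rows], ncomp)
        w = np.abs(coef)

        r = rmsecv(X[:, subset], y, ncomp, fold_id)
        trajectory[run - 1] = r
        if r < best_rmse:
            best_rmse, best_subset, best_weights = r, subset.copy(), w.copy()

        # enforced reduction: keep the top ceil(r_i * p) by |coefficient|
        m_i = max(2, min(subset.size, ceil(edf_ratio(run, n_runs, p) * p)))
        ranked = _rank_by_weight(np.arange(subset.size), w)[:m_i]
        kept = subset[ranked]
        w_kept = w[ranked]
        # adaptive reweighted sampling among the survivors
        total = w_kept.sum()
        probs = w_kept / total if total > 0 else np.full(m_i, 1.0 / m_i)
        draw = rng.choice(m_i, size=m_i, replace=True, p=probs)
        subset = np.unique(kept[draw])
        if subset.size < 2:
            subset = np.sort(kept[:2])

    scores = np.zeros(p)
    ncomp = _inner_ncomp(best_subset.size, n, folds)
    coef, _ = pls1_coefficients(X[:, best_subset], y, ncomp)
    scores[best_subset] = np.abs(coef)
    result = SelectionResult(method="CARS",
                             selected_indices=np.sort(best_subset),
                             scores=scores, rmsecv_best=float(best_rmse),
                             seed=seed, rmsecv_trajectory=trajectory)
    return cap_selection(result, cap) if cap is not None else result


def random_frog_select(X: np.ndarray, y: np.ndarray, n_iter: int = 10_000,
                       threshold: float = 0.40, seed: int = 0,
                       folds: int = 5, q_init: int = 5, eta: float = 0.1,
                       cap: int | None = DEFAULT_CAP) -> SelectionResult:
    """Random-frog selection probabilities over the columns of X.

    The working-subset walk is a reconstruction of the cited algorithm (the
    source describes it only qualitatively): candidate sizes are drawn as
    ``round(|N(Q, 0.3 Q)|)`` clipped to [1, p]; shrinking keeps the top
    variables of the current subset by |PLS coefficient|, growing adds
    uniform draws from the complement, and with probability 1/2 one member is
    swapped for an outside variable. Rejected candidates leave the working
    subset unchanged.
    """
    X, y = _check_xy(X, y, folds)
    if not 0.0 < threshold < 1.0:
        raise SelectionError(f"threshold must lie in (0, 1), got {threshold}")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    fold_id = make_folds(n, folds, rng)
    q_init = max(1, min(q_init, p))

    cache: dict[bytes, float] = {}

    def subset_rmsecv(subset: np.ndarray) -> float:
        key = subset.tobytes()
        if key not in cache:
            ncomp = _inner_ncomp(subset.size, n, folds)
            cache[key] = rmsecv(X[:, subset], y, ncomp, fold_id)
        return cache[key]

    current = np.sort(rng.choice(p, size=q_init, replace=False))
    r_cur = subset_rmsecv(current)
    counts = np.zeros(p)

    all_vars = np.arange(p)
    for _ in range(n_iter):
        q_star = int(np.clip(round(abs(rng.normal(q_init, 0.3 * q_init))), 1, p))
        if q_star < current.size:
            ncomp = _inner_ncomp(current.size, n, folds)
            coef, _ = pls1_coefficients(X[:, current], y, ncomp)
            candidate = _rank_by_weight(current, np.abs(coef))[:q_star]
        elif q_star > current.size:
            outside = np.setdiff1d(all_vars, current, assume_unique=True)
            extra = rng.choice(outside, size=min(q_star - current.size,
                                                 outside.size), replace=False)
            candidate = np.concatenate([current, extra])
        else:
            candidate = current.copy()
        if candidate.size < p and rng.random() < 0.5:
            outside = np.setdiff1d(all_vars, candidate, assume_unique=False)
            candidate = candidate.copy()
            candidate[rng.integers(candidate.size)] = rng.choice(outside)
        candidate = np.unique(candidate)

        r_cand = subset_rmsecv(candidate)
        if r_cand <= r_cur or rng.random() < eta * (r_cur / r_cand):
            current, r_cur = candidate, r_cand
        counts[current] += 1

    probs = counts / n_iter
    selected = np.nonzero(probs >= threshold)[0]
    if selected.size == 0:
        warnings.warn(
            f"no variable reached selection probability {threshold}; "
            "returning an empty selection")
        best = float("nan")
    else:
        best = subset_rmsecv(np.sort(selected))
    result = SelectionResult(method="RF", selected_indices=np.sort(selected),
                             scores=probs, rmsecv_best=best, seed=seed)
    return cap_selection(result, cap) if cap is not None else result


def cap_selection(result: SelectionResult, cap: int = DEFAULT_CAP,
                  ) -> SelectionResult:
    """Keep at most ``cap`` best-scoring selected variables.

    Ranking is by descending score (|coefficient| for CARS, probability for
    RF); exact ties at the cap boundary are broken toward the lower variable
    index.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    sel = result.selected_indices
    if sel.size <= cap:
        return result
    kept = _rank_by_weight(sel, result.scores[sel])[:cap]
    return replace(result, selected_indices=np.sort(kept))
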