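"""PLSR modeling of leaf potassium: splitting, fitting, metrics, fusion.

Samples are split 2:1 into calibration and validation sets by the
concentration-gradient rule: sort by K, send the middle sample of each
consecutive block of three to validation, and force the global K extremes
into calibration so the calibration range covers the validation range
(60 samples -> 40/20).

Models are partial least squares regressions (mean-centered, no
unit-variance scaling); the latent-variable count minimizes 5-fold RMSECV.
Performance is reported as

    R^2   = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2
    RMSE  = sqrt( (1/n) sum (y_i - yhat_i)^2 )

on the designated sample set (no adjustment). The comparison harness mirrors
the study's two report surfaces: the raw spectrum R plus the ten CWT scales
per selector, then — for the best scale — the four fusion combinations
{spectra, +color, +texture, +color+texture}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from ._pls import make_folds

__all__ = [
    "SplitResult",
    "PLSRModel",
    "ModelResult",
    "ComparisonReport",
    "ModelError",
    "concentration_gradient_split",
    "fit_plsr",
    "evaluate_metrics",
    "fit_and_evaluate",
    "fuse_and_compare",
]


class ModelError(RuntimeError):
    pass


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/validation sample-id partition."""

    calibration_ids: tuple
    validation_ids: tuple

    def __post_init__(self) -> None:
        overlap = set(self.calibration_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"calibration/validation overlap: {overlap}")


def concentration_gradient_split(k_values: Sequence[float],
                                 sample_ids: Sequence | None = None,
                                 ) -> SplitResult:
    """2:1 concentration-gradient calibration/validation split.

    Sort samples by K ascending; within each consecutive block of three the
    middle sample goes to validation (any remainder goes to calibration).
    The samples holding the global minimum and maximum K are forced into
    calibration, swapping with their nearest calibration neighbor if the
    block rule ever placed them in validation.
    """
    k = np.asarray(k_values, dtype=float)
    if k.size < 3:
        raise ValueError("need at least 3 samples to split")
    if not np.all(np.isfinite(k)):
        raise ValueError("K values must be finite")
    if sample_ids is None:
        ids = list(range(k.size))
    else:
        ids = list(sample_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if len(ids) != k.size:
            raise ValueError("ids and K values disagree in length")

    order = np.argsort(k, kind="stable")
    val_pos = {order[b + 1] for b in range(0, k.size - k.size % 3, 3)}
    # force global extremes into calibration
    for extreme in (order[0], order[-1]):
        if extreme in val_pos:
            val_pos.discard(extreme)
            k_e = k[extreme]
            cal = [i for i in range(k.size) if i not in val_pos and i != extreme]
            if cal:
                val_pos.add(min(cal, key=lambda i: abs(k[i] - k_e)))
    cal_ids = tuple(ids[i] for i in range(k.size) if i not in val_pos)
    val_ids = tuple(ids[i] for i in sorted(val_pos))
    return SplitResult(calibration_ids=cal_ids, validation_ids=val_ids)


def evaluate_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                     ) -> tuple[float, float]:
    """Determination coefficient and RMSE (population forms, no adjustment)."""
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y_true and y_pred must share a length of >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ModelError("y_true has zero variance; R^2 undefined")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst, float(np.sqrt(sse / y.size))


@dataclass
class PLSRModel:
    """A fitted mean-centered PLS regression."""

    n_latent: int
    coefficients: np.ndarray
    intercept: float
    _sk: PLSRegression = field(repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept


def _lv_cap(n: int, p: int, folds: int, max_lv: int) -> int:
    return max(1, min(max_lv, p, n - ceil(n / folds) - 1))


def fit_plsr(X: np.ndarray, y: np.ndarray, folds: int = 5, max_lv: int = 10,
             seed: int = 0) -> PLSRModel:
    """Fit PLSR with the latent-variable count chosen by 5-fold RMSECV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape if X.ndim == 2 else (X.shape[0], 0)
    if p == 0:
        raise ModelError("empty feature matrix (no columns to fit)")
    if n < folds:
        raise ModelError(f"need at least {folds} samples for {folds}-fold CV")
    if np.ptp(y) <= 0:
        raise ModelError("constant response")
    cap = _lv_cap(n, p, folds, max_lv)
    fold_id = make_folds(n, folds, np.random.default_rng(seed))
    press = np.zeros(cap)
    for f in np.unique(fold_id):
        test = fold_id == f
        train = ~test
        cap_f = _lv_cap(int(train.sum()), p, folds, cap)
        for a in range(1, cap + 1):
            sk = PLSRegression(n_components=min(a, cap_f), scale=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sk.fit(X[train], y[train])
            resid = y[test] - sk.predict(X[test]).ravel()
            press[a - 1] += float(resid @ resid)
    best_a = int(np.argmin(press)) + 1
    sk = PLSRegression(n_components=best_a, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sk.fit(X, y)
    coef = np.asarray(sk.coef_).reshape(-1)
    # express the centered fit as y = X @ coef + intercept in raw coordinates
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    return PLSRModel(n_latent=best_a, coefficients=coef, intercept=intercept,
                     _sk=sk)


@dataclass(frozen=True)
class ModelResult:
    """Calibration/validation performance of one feature combination."""

    feature_set: str
    n_features: int
    n_latent: int
    r2_cal: float
    rmse_cal: float
    r2_val: float
    rmse_val: float
    degraded: bool = False  # True when a fusion table was empty

    def as_row(self) -> dict:
        return {
            "feature_set": self.feature_set, "n_features": self.n_features,
            "n_latent": self.n_latent, "r2_cal": self.r2_cal,
            "rmse_cal": self.rmse_cal, "r2_val": self.r2_val,
            "rmse_val": self.rmse_val, "degraded": self.degraded,
        }


def fit_and_evaluate(X_cal: np.ndarray, y_cal: np.ndarray, X_val: np.ndarray,
                     y_val: np.ndarray, feature_set: str, folds: int = 5,
                     max_lv: int = 10, seed: int = 0,
                     degraded: bool = False) -> ModelResult:
    """Fit on calibration rows, evaluate on both sets, package the metrics."""
    model = fit_plsr(X_cal, y_cal, folds=folds, max_lv=max_lv, seed=seed)
    r2c, rmsec = evaluate_metrics(y_cal, model.predict(X_cal))
    r2v, rmsev = evaluate_metrics(y_val, model.predict(X_val))
    return ModelResult(feature_set=feature_set, n_features=X_cal.shape[1],
                       n_latent=model.n_latent, r2_cal=r2c, rmse_cal=rmsec,
                       r2_val=r2v, rmse_val=rmsev, degraded=degraded)


@dataclass
class ComparisonReport:
    """The two report surfaces of the comparison harness.

    ``spectral`` has one row per (selector, feature set) for the raw spectrum
    R and each CWT scale; ``fusion`` has the four combination rows built on
    the best spectral row. Best rows are chosen by highest validation R^2,
    ties by lower validation RMSE, then fewer features.
    """

    spectral: pd.DataFrame
    fusion: pd.DataFrame
    best_selector: str
    best_feature_set: str
    best_combination: str


def _better(row_a: dict, row_b: dict | None) -> bool:
    if row_b is None:
        return True
    ka = (-row_a["r2_val"], row_a["rmse_val"], row_a["n_features"])
    kb = (-row_b["r2_val"], row_b["rmse_val"], row_b["n_features"])
    return ka < kb


def _aligned(tables: Sequence[pd.DataFrame]) -> None:
    base = tables[0].index
    for t in tables[1:]:
        if not t.index.equals(base):
            raise ModelError("feature tables are not row-aligned by sample id")


def fuse_and_compare(spectral_tables: Mapping[tuple[str, str], pd.DataFrame],
                     color: pd.DataFrame | None,
                     texture: pd.DataFrame | None,
                     k: pd.Series, split: SplitResult,
                     folds: int = 5, max_lv: int = 10,
                     seed: int = 0) -> ComparisonReport:
    """Run the scale/selector comparison, then the fusion combinations.

    ``spectral_tables`` maps ``(selector, feature_set)`` — e.g.
    ``("CARS", "CWT-9")`` or ``("RF", "R")`` — to sample-by-feature tables of
    the selected characteristic wavelengths. ``color`` / ``texture`` hold the
    screened image features (``None`` or zero columns degrade fusion to
    spectra-only).
    """
    all_tables = list(spectral_tables.values()) + [
        t for t in (color, texture) if t is not None]
    if not all_tables:
        raise ModelError("no spectral tables supplied")
    _aligned(all_tables + [k.to_frame()])

    cal = list(split.calibration_ids)
    val = list(split.validation_ids)
    y_cal = k.loc[cal].to_numpy(dtype=float)
    y_val = k.loc[val].to_numpy(dtype=float)

    def run(table: pd.DataFrame, name: str, degraded: bool = False) -> dict:
        res = fit_and_evaluate(table.loc[cal].to_numpy(dtype=float), y_cal,
                               table.loc[val].to_numpy(dtype=float), y_val,
                               feature_set=name, folds=folds, max_lv=max_lv,
                               seed=seed, degraded=degraded)
        return res.as_row()

    spectral_rows = []
    best = None
    best_key: tuple[str, str] | None = None
    for (selector, label), table in spectral_tables.items():
        if table.shape[1] == 0:
            warnings.warn(f"{selector}/{label}: empty selection, skipped")
            continue
        row = run(table, label)
        row["selector"] = selector
        spectral_rows.append(row)
        if _better(row, best):
            best, best_key = row, (selector, label)
    if best is None:
        raise ModelError("every spectral selection was empty")
    best_selector, best_label = best_key
    base_table = spectral_tables[best_key]

    def maybe(df: pd.DataFrame | None) -> pd.DataFrame:
        return df if df is not None else pd.DataFrame(index=base_table.index)

    color_t, texture_t = maybe(color), maybe(texture)
    combos = [
        (best_label, [base_table]),
        (f"{best_label} + color", [base_table, color_t]),
        (f"{best_label} + texture", [base_table, texture_t]),
        (f"{best_label} + color + texture", [base_table, color_t, texture_t]),
    ]
    fusion_rows = []
    best_combo = None
    best_combo_name = best_label
    for name, parts in combos:
        joined = pd.concat(parts, axis=1)
        degraded = joined.shape[1] == base_table.shape[1] and name != best_label
        row = run(joined, name, degraded=degraded)
        row["selector"] = best_selector
        fusion_rows.append(row)
        if _better(row, best_combo):
            best_combo, best_combo_name = row, name

    cols = ["selector", "feature_set", "n_features", "n_latent", "r2_cal",
            "rmse_cal", "r2_val", "rmse_val", "degraded"]
    return ComparisonReport(
        spectral=pd.DataFrame(spectral_rows)[cols],
        fusion=pd.DataFrame(fusion_rows)[cols],
        best_selector=best_selector,
        best_feature_set=best_label,
        best_combination=best_combo_name,
    )
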