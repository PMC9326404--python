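"""Masked texture and color features of characteristic-wavelength images.

Texture comes from gray-level co-occurrence matrices (GLCM) computed over the
leaf mask only: a pair of pixels contributes only if *both* lie inside the
mask. Per image and angle (0, 45, 90, 135 degrees; step 1; 256 gray levels)
four statistics are computed,

    ENE = sum_ij P(i,j)^2                      (energy)
    ENT = -sum_ij P(i,j) ln P(i,j)             (entropy, 0 ln 0 := 0)
    CON = sum_ij P(i,j) (i - j)^2              (contrast)
    COR = sum_ij P(i,j)(i - mu_i)(j - mu_j) / sqrt(var_i var_j)

plus the mean and variance of each statistic across the four angles, giving
24 (4 x 4 + 8) texture features per image. Color features are the first
three moments of the masked gray-level distribution (mean MEA, spread VAR as
root mean square deviation, asymmetry SKE as signed cube root of the third
central moment) — 3 per image.

Feature names follow the "wavelength-statistic-direction" scheme, e.g.
``641 nm-CON-135°``, ``532 nm-VAR``, ``594 nm-MEA (CON)``.

Screening: features are first kept if their Pearson correlation with leaf
potassium is significant at p < 0.05, then CARS picks the final small set
among the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .selection import SelectionResult, cars_select, DEFAULT_CAP

__all__ = [
    "ANGLES",
    "GLCMStatistics",
    "ColorMoments",
    "PairCountError",
    "glcm_matrix",
    "glcm_stats",
    "texture_features",
    "color_moments",
    "color_features",
    "screen_image_features",
]

ANGLES = (0, 45, 90, 135)
_STAT_NAMES = ("ENE", "ENT", "CON", "COR")

# pixel offset (drow, dcol) per angle at unit distance
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class PairCountError(RuntimeError):
    """No valid in-mask pixel pair exists at the requested offset."""


@dataclass(frozen=True)
class GLCMStatistics:
    """The four co-occurrence statistics plus the marginals used inside COR."""

    ENE: float
    ENT: float
    CON: float
    COR: float
    MEA: float  # marginal mean of the (symmetric) GLCM
    VAR: float  # marginal variance of the (symmetric) GLCM
    degenerate: bool = False  # True when var_i * var_j = 0 (COR set to 0)


@dataclass(frozen=True)
class ColorMoments:
    """Low-order gray-level moments of a masked single-channel image."""

    MEA: float
    VAR: float
    SKE: float


def glcm_matrix(image: np.ndarray, mask: np.ndarray, angle: int,
                distance: int = 1, levels: int = 256) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix over the masked region.

    Counts ordered pairs ``(p, p + offset)`` with both pixels inside the
    mask, adds the transpose (symmetrization) and normalizes to sum 1.
    """
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {ANGLES}, got {angle}")
    img = np.asarray(image)
    if img.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    if img.min() < 0 or img.max() >= levels:
        raise ValueError(f"gray levels must lie in [0, {levels})")
    dr, dc = _OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    rows, cols = img.shape

    r0 = slice(max(0, -dr), min(rows, rows - dr))
    c0 = slice(max(0, -dc), min(cols, cols - dc))
    r1 = slice(max(0, dr), min(rows, rows + dr))
    c1 = slice(max(0, dc), min(cols, cols + dc))

    both = mask[r0, c0] & mask[r1, c1]
    i_vals = img[r0, c0][both].astype(np.intp)
    j_vals = img[r1, c1][both].astype(np.intp)
    if i_vals.size == 0:
        raise PairCountError(
            f"no valid in-mask pixel pair at angle {angle}°, distance {distance}")
    counts = np.zeros((levels, levels))
    np.add.at(counts, (i_vals, j_vals), 1.0)
    counts += counts.T.copy()
    return counts / counts.sum()


def glcm_stats(P: np.ndarray) -> GLCMStatistics:
    """Energy, entropy, contrast and correlation of a normalized GLCM."""
    P = np.asarray(P, dtype=float)
    if abs(P.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized to sum 1")
    k = P.shape[0]
    idx = np.arange(k, dtype=float)
    ene = float(np.sum(P * P))
    nz = P > 0
    ent = float(-np.sum(P[nz] * np.log(P[nz])))
    con = float(np.sum(P * (idx[:, None] - idx[None, :]) ** 2))
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mi = float(idx @ pi)
    mj = float(idx @ pj)
    vi = float(((idx - mi) ** 2) @ pi)
    vj = float(((idx - mj) ** 2) @ pj)
    if vi * vj <= 0:
        return GLCMStatistics(ENE=ene, ENT=ent, CON=con, COR=0.0, MEA=mi,
                              VAR=vi, degenerate=True)
    cor = float(np.sum(P * np.outer(idx - mi, idx - mj)) / np.sqrt(vi * vj))
    return GLCMStatistics(ENE=ene, ENT=ent, CON=con, COR=cor, MEA=mi, VAR=vi)


def _prefix(wavelength_nm: float | None) -> str:
    if wavelength_nm is None:
        return ""
    w = float(wavelength_nm)
    return f"{w:g} nm-"


def texture_features(image: np.ndarray, mask: np.ndarray,
                     wavelength_nm: float | None = None, distance: int = 1,
                     levels: int = 256) -> pd.Series:
    """The 24 texture features of one masked grayscale image.

    Four statistics at four angles (16) plus the mean and (population)
    variance of each statistic across angles (8), named
    ``{λ} nm-{STAT}-{angle}°`` and ``{λ} nm-MEA ({STAT})`` /
    ``{λ} nm-VAR ({STAT})``.
    """
    pre = _prefix(wavelength_nm)
    per_angle = {
        a: glcm_stats(glcm_matrix(image, mask, a, distance, levels))
        for a in ANGLES
    }
    out: dict[str, float] = {}
    for stat in _STAT_NAMES:
        for a in ANGLES:
            out[f"{pre}{stat}-{a}°"] = getattr(per_angle[a], stat)
    for stat in _STAT_NAMES:
        vals = np.array([getattr(per_angle[a], stat) for a in ANGLES])
        out[f"{pre}MEA ({stat})"] = float(vals.mean())
        out[f"{pre}VAR ({stat})"] = float(vals.var())
    return pd.Series(out)


def color_moments(image: np.ndarray, mask: np.ndarray) -> ColorMoments:
    """First three gray-level moments of the masked region."""
    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    vals = np.asarray(image, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty mask")
    mea = float(vals.mean())
    dev = vals - mea
    var = float(np.sqrt(np.mean(dev ** 2)))
    ske = float(np.cbrt(np.mean(dev ** 3)))
    return ColorMoments(MEA=mea, VAR=var, SKE=ske)


def color_features(image: np.ndarray, mask: np.ndarray,
                   wavelength_nm: float | None = None) -> pd.Series:
    """The 3 color-moment features of one image, named ``{λ} nm-{MOMENT}``."""
    pre = _prefix(wavelength_nm)
    m = color_moments(image, mask)
    return pd.Series({f"{pre}MEA": m.MEA, f"{pre}VAR": m.VAR,
                      f"{pre}SKE": m.SKE})


def correlation_pvalues(table: pd.DataFrame, k_values: np.ndarray,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every column with K, and two-sided p-values."""
    X = table.to_numpy(dtype=float)
    k = np.asarray(k_values, dtype=float)
    n = k.size
    kc = k - k.mean()
    Xc = X - X.mean(axis=0)
    ss = np.einsum("sf,sf->f", Xc, Xc)
    denom = np.sqrt(np.where(ss > 0, ss, 1.0) * (kc @ kc))
    r = np.where(ss > 0, (kc @ Xc) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * _stats.t.sf(np.abs(t), df=n - 2)
    p[ss <= 0] = 1.0
    return r, p


def screen_image_features(table: pd.DataFrame, k_values: np.ndarray,
                          seed: int = 0, alpha: float = 0.05,
                          cap: int = DEFAULT_CAP) -> SelectionResult:
    """Two-stage screening of an image-feature table against K.

    Stage 1 keeps features whose Pearson correlation with K is significant at
    ``p < alpha``; stage 2 runs CARS on the survivors. Returns a
    :class:`SelectionResult` whose indices refer to the columns of ``table``
    (empty, with a warning from the caller's side, when nothing survives —
    fusion then degrades to spectra-only).
    """
    k = np.asarray(k_values, dtype=float)
    if table.shape[0] != k.size:
        raise ValueError("feature table and K vector disagree on samples")
    if table.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    r, p = correlation_pvalues(table, k)
    survivors = np.nonzero(p < alpha)[0]
    scores = np.zeros(table.shape[1])
    if survivors.size == 0:
        return SelectionResult(method="CARS",
                               selected_indices=np.array([], dtype=int),
                               scores=scores, rmsecv_best=float("nan"),
                               seed=seed)
    if survivors.size < 3:
        scores[survivors] = np.abs(r[survivors])
        return SelectionResult(method="CARS", selected_indices=survivors,
                               scores=scores, rmsecv_best=float("nan"),
                               seed=seed)
    sub = cars_select(table.to_numpy(dtype=float)[:, survivors], k, seed=seed,
                      cap=cap)
    scores[survivors] = sub.scores
    return SelectionResult(method="CARS",
                           selected_indices=survivors[sub.selected_indices],
                           scores=scores, rmsecv_best=sub.rmsecv_best,
                           seed=seed)
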