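"""Continuous wavelet transform of reflectance spectra at dyadic scales.

A spectrum f(lambda) is projected onto translated/dilated copies of the sym2
mother wavelet,

    W_f(a, b) = sum_lambda f(lambda) * psi_ab(lambda),
    psi_ab(lambda) = a^{-1/2} * psi((lambda - b) / a),

discretized over the band index (the grid is uniform, so band index and nm
are equivalent up to a relabeling of scale). Scales are dyadic, a = 2^i for
i = 1..10 ("CWT-i"); the result for one spectrum is an m x n matrix of
coefficients (m scales by n bands). Boundaries use symmetric (mirror)
extension so spectrum edges do not masquerade as red-edge features.

The mother wavelet is sampled once by cascade refinement
(``pywt.Wavelet("sym2").wavefun``) on a dense grid (2^12 points across its
support), recentred on the midpoint of its support, and linearly
interpolated at each scale's sample points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt

from .grid import WavelengthGrid
from .simulate import HyperCube

__all__ = [
    "WaveletCoefficients",
    "CorrelationMap",
    "SupportError",
    "cwt_spectrum",
    "cwt_matrix",
    "correlation_map",
    "coefficient_image",
]

DEFAULT_SCALE_EXPONENTS = tuple(range(1, 11))  # a = 2^1 .. 2^10


class SupportError(ValueError):
    """Spectrum shorter than the effective wavelet support."""


@dataclass(frozen=True)
class WaveletCoefficients:
    """Scale-by-band coefficient matrix W_f(a, b) for one spectrum."""

    coefficients: np.ndarray  # (m scales, n bands)
    scale_exponents: tuple[int, ...]  # a = 2^i
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        m, n = self.coefficients.shape
        if m != len(self.scale_exponents) or n != len(self.grid):
            raise ValueError("coefficient matrix shape does not match "
                             "scales/grid")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite wavelet coefficients")

    def at_scale(self, exponent: int) -> np.ndarray:
        return self.coefficients[self.scale_exponents.index(exponent)]


@dataclass(frozen=True)
class CorrelationMap:
    """|Pearson r| between W_f(a, b) and K across samples, per (scale, band)."""

    abs_r: np.ndarray  # (m, n) in [0, 1]
    scale_exponents: tuple[int, ...]
    grid: WavelengthGrid
    n_samples: int
    degenerate: np.ndarray  # True where a coefficient column had zero variance

    def per_scale_maxima(self) -> np.ndarray:
        return self.abs_r.max(axis=1)


@lru_cache(maxsize=1)
def _sym2_centered() -> tuple[np.ndarray, np.ndarray]:
    """sym2 psi sampled densely by cascade refinement, support centered at 0."""
    wavelet = pywt.Wavelet("sym2")
    _, psi, x = wavelet.wavefun(level=12)
    x = np.asarray(x, dtype=float)
    mid = 0.5 * (x[0] + x[-1])
    return x - mid, np.asarray(psi, dtype=float)


@lru_cache(maxsize=32)
def _kernel(scale: int) -> np.ndarray:
    """Discrete wavelet kernel k[d] = psi(d / a) / sqrt(a), d = -h..h."""
    xc, psi = _sym2_centered()
    half_support = xc[-1]  # 1.5 for sym2
    h = int(np.ceil(half_support * scale))
    d = np.arange(-h, h + 1, dtype=float)
    vals = np.interp(d / scale, xc, psi, left=0.0, right=0.0)
    return vals / np.sqrt(scale)


def _mirror_indices(idx: np.ndarray, n: int) -> np.ndarray:
    """Map out-of-range indices by symmetric (mirror-with-repeat) extension."""
    period = 2 * n
    m = np.mod(idx, period)
    return np.where(m < n, m, period - 1 - m)


def cwt_spectrum(spectrum: np.ndarray,
                 scale_exponents: tuple[int, ...] = DEFAULT_SCALE_EXPONENTS,
                 grid: WavelengthGrid | None = None) -> WaveletCoefficients:
    """CWT of one spectrum at dyadic scales 2^i.

    The transform is linear in the spectrum. Returns the m x n coefficient
    matrix with rows ordered as ``scale_exponents``.
    """
    f = np.asarray(spectrum, dtype=float)
    if f.ndim != 1:
        raise ValueError("spectrum must be 1-D")
    n = f.size
    if n < 4:
        raise SupportError(
            f"spectrum of length {n} is shorter than the sym2 support at the "
            "smallest scale")
    bad = [i for i in scale_exponents if not 1 <= i <= 10]
    if bad:
        raise ValueError(f"scale exponents must lie in 1..10, got {bad}")
    if grid is None:
        grid = WavelengthGrid(np.arange(n, dtype=float))
    rows = []
    for i in scale_exponents:
        k = _kernel(2 ** i)
        h = (k.size - 1) // 2
        f_ext = np.pad(f, h, mode="symmetric")
        rows.append(np.correlate(f_ext, k, mode="valid"))
    return WaveletCoefficients(np.vstack(rows), tuple(scale_exponents), grid)


def cwt_matrix(spectra: np.ndarray,
               scale_exponents: tuple[int, ...] = DEFAULT_SCALE_EXPONENTS,
               ) -> np.ndarray:
    """CWT of many spectra at once: (samples, bands) -> (samples, m, n)."""
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    n = X.shape[1]
    if n < 4:
        raise SupportError("spectra shorter than the sym2 support")
    out = np.empty((X.shape[0], len(scale_exponents), n))
    for si, i in enumerate(scale_exponents):
        k = _kernel(2 ** i)
        h = (k.size - 1) // 2
        idx = _mirror_indices(np.arange(-h, n + h), n)
        Xe = X[:, idx]
        # correlation of every row with the kernel, valid region
        for b in range(n):
            out[:, si, b] = Xe[:, b:b + k.size] @ k
    return out


def correlation_map(coeff_stack, k_values: np.ndarray,
                    grid: WavelengthGrid | None = None) -> CorrelationMap:
    """Absolute Pearson correlation between coefficients and K per (scale, band).

    ``coeff_stack`` is either the (samples, m, n) array from
    :func:`cwt_matrix` or a sequence of :class:`WaveletCoefficients` sharing
    scales and grid. Zero-variance coefficient columns get |R| = 0 and are
    flagged in ``degenerate``.
    """
    if isinstance(coeff_stack, np.ndarray):
        C = coeff_stack
        exponents = DEFAULT_SCALE_EXPONENTS[:C.shape[1]]
        if grid is None:
            grid = WavelengthGrid(np.arange(C.shape[2], dtype=float))
    else:
        stack = list(coeff_stack)
        C = np.stack([w.coefficients for w in stack])
        exponents = stack[0].scale_exponents
        grid = stack[0].grid
    k = np.asarray(k_values, dtype=float)
    if C.shape[0] != k.size:
        raise ValueError("coefficient stack and K vector disagree on samples")
    if C.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation map")
    kc = k - k.mean()
    k_ss = float(kc @ kc)
    if k_ss <= 0:
        raise ValueError("K values have zero variance")
    Cc = C - C.mean(axis=0)
    cov = np.einsum("s,smn->mn", kc, Cc)
    ss = np.einsum("smn,smn->mn", Cc, Cc)
    degenerate = ss <= 0
    denom = np.sqrt(np.where(degenerate, 1.0, ss) * k_ss)
    abs_r = np.where(degenerate, 0.0, np.abs(cov) / denom)
    return CorrelationMap(abs_r=np.clip(abs_r, 0.0, 1.0),
                          scale_exponents=tuple(exponents), grid=grid,
                          n_samples=int(C.shape[0]), degenerate=degenerate)


def coefficient_image(cube: HyperCube, mask: np.ndarray, scale_exponent: int,
                      wavelength: float, raw_band: bool = False) -> np.ndarray:
    """8-bit grayscale image of per-pixel CWT coefficients at one band.

    Computes the spectral-axis CWT at scale 2^i for every masked pixel, takes
    the coefficient at the band nearest ``wavelength``, min-max scales it over
    the masked pixels to 0-255 and zeroes the background. With
    ``raw_band=True`` the reflectance band image itself is scaled instead.
    Min-max scaling makes the image invariant to any global gain.
    """
    if mask.shape != cube.values.shape[:2]:
        raise ValueError("mask/cube shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    n = len(cube.grid)
    b0 = cube.grid.nearest_index(wavelength)
    if raw_band:
        field = cube.values[:, :, b0].astype(float)
    else:
        k = _kernel(2 ** scale_exponent)
        h = (k.size - 1) // 2
        idx = _mirror_indices(b0 + np.arange(-h, h + 1), n)
        # fold the kernel onto the n bands touched through mirror extension
        w = np.zeros(n)
        np.add.at(w, idx, k)
        field = cube.values.reshape(-1, n).astype(float) @ w
        field = field.reshape(cube.values.shape[:2])
    vals = field[mask]
    lo, hi = float(vals.min()), float(vals.max())
    img = np.zeros(mask.shape, dtype=np.uint8)
    if hi - lo <= 0:
        warnings.warn("constant coefficient field over mask; image is all zero")
        return img
    img[mask] = np.round((field[mask] - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return img
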