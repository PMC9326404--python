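"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities by direct enumeration or
literal formula evaluation, independent of the library's vectorized paths.
"""

from __future__ import annotations

import numpy as np
import pytest
import pywt

import leafspec as ls


# ---------------------------------------------------------------- oracles

def mirror_index(i: int, n: int) -> int:
    """Symmetric (mirror-with-repeat) boundary index, matching np.pad."""
    m = i % (2 * n)
    return m if m < n else 2 * n - 1 - m


def brute_force_cwt(spectrum: np.ndarray, scale_exponent: int) -> np.ndarray:
    """Direct discretized-integral CWT: explicit sum over translations."""
    wavelet = pywt.Wavelet("sym2")
    _, psi, x = wavelet.wavefun(level=12)
    xc = x - 0.5 * (x[0] + x[-1])
    a = 2 ** scale_exponent
    n = spectrum.size
    h = int(np.ceil(xc[-1] * a))
    out = np.empty(n)
    for b in range(n):
        total = 0.0
        for d in range(-h, h + 1):
            total += (spectrum[mirror_index(b + d, n)]
                      * np.interp(d / a, xc, psi, left=0.0, right=0.0)
                      / np.sqrt(a))
        out[b] = total
    return out


def brute_force_glcm(image: np.ndarray, mask: np.ndarray, angle: int,
                     distance: int = 1, levels: int = 256) -> np.ndarray:
    """Pair enumeration over every pixel, symmetrized and normalized."""
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = offsets[angle]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((levels, levels))
    rows, cols = image.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                counts[image[r, c], image[r2, c2]] += 1
                counts[image[r2, c2], image[r, c]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs")
    return counts / total


def brute_force_glcm_stats(P: np.ndarray) -> dict[str, float]:
    """Double-loop evaluation of the co-occurrence statistics."""
    k = P.shape[0]
    ene = ent = con = mi = mj = 0.0
    for i in range(k):
        for j in range(k):
            p = P[i, j]
            ene += p * p
            if p > 0:
                ent -= p * np.log(p)
            con += p * (i - j) ** 2
            mi += p * i
            mj += p * j
    vi = vj = cov = 0.0
    for i in range(k):
        for j in range(k):
            p = P[i, j]
            vi += p * (i - mi) ** 2
            vj += p * (j - mj) ** 2
            cov += p * (i - mi) * (j - mj)
    cor = cov / np.sqrt(vi * vj) if vi * vj > 0 else 0.0
    return {"ENE": ene, "ENT": ent, "CON": con, "COR": cor,
            "MEA": mi, "VAR": vi}


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def default_grid():
    return ls.make_band_grid()


@pytest.fixture(scope="session")
def small_scene_config():
    """Desk-scale scene used by most rendering tests."""
    return ls.SceneConfig(image_shape=(96, 96), n_leaves_per_stage=12)


@pytest.fixture(scope="session")
def noiseless_scene(small_scene_config):
    """A rendered scene with every stochastic amplitude at zero."""
    cfg = ls.noiseless_config(image_shape=(96, 96), n_leaves_per_stage=12)
    cube, mask, truth = ls.render_scene(cfg, 1.2, seed=5)
    return cfg, cube, mask, truth


@pytest.fixture(scope="session")
def default_scene():
    cfg = ls.SceneConfig()
    cube, mask, truth = ls.render_scene(cfg, 1.2, seed=5)
    return cfg, cube, mask, truth
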