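"""Uniform band-center wavelength grids for line-scan hyperspectral sensors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidConfigError(ValueError):
    """Raised when a grid or scene configuration is internally inconsistent."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered, uniformly spaced band centers in nanometres.

    The default sensor layout is 128 bands starting at 376 nm with 5.2 nm
    spacing, covering the visible and near-infrared range; analysis normally
    trims this to the 400-950 nm window (106 bands).
    """

    centers: np.ndarray
    spacing: float = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise InvalidConfigError("grid needs at least one band center")
        d = np.diff(c)
        if c.size > 1:
            if np.any(d <= 0):
                raise InvalidConfigError("band centers must be strictly increasing")
            # sensor grids are uniform; ad-hoc grids may not be
            spacing = float(d[0]) if np.max(np.abs(d - d[0])) <= 1e-9 else float("nan")
        else:
            spacing = 0.0
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "spacing", spacing)

    def __len__(self) -> int:
        return self.centers.size

    def nearest_index(self, wavelength_nm: float) -> int:
        """Index of the band center closest to ``wavelength_nm``.

        Ties between two equidistant centers go to the lower center.
        """
        d = np.abs(self.centers - float(wavelength_nm))
        return int(np.argmin(d))  # argmin returns first (lower) index on ties

    def window_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of centers c with lo <= c <= hi (closed interval)."""
        return np.nonzero((self.centers >= lo_nm) & (self.centers <= hi_nm))[0]


def make_band_grid(n_bands: int = 128, start_nm: float = 376.0,
                   spacing_nm: float = 5.2) -> WavelengthGrid:
    """Build a uniform band grid: centers[i] = start + i * spacing.

    Defaults emulate a 128-band VNIR imaging spectrometer whose 400-950 nm
    window retains 106 bands.
    """
    if n_bands < 2:
        raise InvalidConfigError(f"need at least 2 bands, got {n_bands}")
    if spacing_nm <= 0:
        raise InvalidConfigError(f"band spacing must be positive, got {spacing_nm}")
    centers = start_nm + spacing_nm * np.arange(n_bands, dtype=float)
    return WavelengthGrid(centers)
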